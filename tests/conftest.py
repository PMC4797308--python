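import numpy as np
import pandas as pd
import pytest

from crichsplice.sim import (
    SimConfig,
    simulate_eclip_reads,
    simulate_expression_table,
    simulate_genome,
    simulate_splicing_table,
)


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic study shared across tests (60 genes, seed 7)."""
    cfg = SimConfig(n_genes=60, n_eclip_reads=5000, seed=7)
    genome, annotation, truth = simulate_genome(cfg)
    return cfg, genome, annotation, truth


@pytest.fixture(scope="session")
def small_sim_tables(small_sim):
    cfg, genome, annotation, truth = small_sim
    events = simulate_splicing_table(cfg, truth)
    fpkm = simulate_expression_table(cfg, truth)
    return cfg, truth, events, fpkm


@pytest.fixture(scope="session")
def small_sim_eclip(small_sim):
    cfg, genome, annotation, truth = small_sim
    reads, crosslinks, peaks = simulate_eclip_reads(cfg, genome, annotation, truth)
    return cfg, genome, truth, reads, crosslinks, peaks


def make_classified_frame(rows):
    """Build a minimal classified-events frame from (delta, fdr, fpkm, psi_kd, psi_ctrl) specs."""
    recs = []
    for i, (delta, fdr, fpkm, psi_kd, psi_ctrl) in enumerate(rows):
        recs.append(
            dict(
                event_id=f"ev{i:03d}",
                gene_id=f"g{i:03d}",
                chrom="ctg1",
                strand="+",
                exon_start=1000 + 500 * i,
                exon_end=1100 + 500 * i,
                fdr=fdr,
                psi_kd=psi_kd,
                psi_ctrl=psi_ctrl,
                delta_psi=delta,
                fpkm_max=fpkm,
            )
        )
    return pd.DataFrame(recs)


def rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
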
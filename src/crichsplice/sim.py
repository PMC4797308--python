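"""Synthetic toy genome, splicing tables and eCLIP reads with planted truth.

The generator emulates the study design the downstream analysis assumes: a
set of multi-exon genes, each with one internal cassette exon, partitioned
into regulator-*enhanced*, regulator-*repressed* and *background* exons. A
C-rich polypyrimidine motif realization is planted in the intron upstream of
the splice acceptor of every enhanced exon (optionally also downstream of
its donor); repressed and background exons instead carry a canonical U-rich
tract at the same position. Replicate knockdown/control junction-count
tables are drawn binomially around group-specific inclusion levels, and
eCLIP-style reads start one nucleotide 3' of crosslink positions that are
enriched at the planted U-rich tracts.

All randomness flows from one seeded ``numpy`` generator: an identical
``SimConfig`` (seed included) yields byte-identical FASTA/GTF/TSV/FASTQ/BED
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .motifs import C_RICH_PATTERN, DegenerateMotif, get_motif

#: U-rich tract (poly-U with interspersed C) planted at repressed/background
#: acceptors; contains the canonical U2AF65 recognition element.
U_TRACT = "UUUUUCUUUUUCUUUU"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the regime the analysis is designed for: deeply
    sequenced junctions (1000 per replicate), three replicates per
    condition, a planted inclusion-level shift of +/-0.3, clearly separated
    FDR strata, and 10x crosslink enrichment at U-rich tracts.
    """

    n_genes: int = 200
    exons_per_gene: int = 3
    intron_length: int = 600
    exon_length: int = 120
    flank_length: int = 300
    frac_enhanced: float = 0.15
    frac_repressed: float = 0.05
    frac_minus_strand: float = 0.3
    planted_motif_5p: str = C_RICH_PATTERN
    planted_offset_5p: int = 30
    planted_motif_3p: Optional[str] = None
    planted_offset_3p: int = 30
    planted_sides_counts: Optional[tuple[int, int, int, int]] = None
    delta_psi_enhanced: float = -0.3
    delta_psi_repressed: float = 0.3
    psi_control: float = 0.5
    replicates_per_group: int = 3
    mean_junction_depth: int = 1000
    fdr_signal: float = 0.01
    fdr_null: float = 0.9
    fpkm_low: float = 10.0
    fpkm_high: float = 100.0
    n_eclip_reads: int = 20000
    read_length: int = 40
    barcode_length: int = 10
    eclip_enrichment: float = 10.0
    frac_duplicates: float = 0.2
    frac_qc_fail: float = 0.1
    base_gc: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        errs = []
        for name in (
            "n_genes",
            "exons_per_gene",
            "intron_length",
            "exon_length",
            "flank_length",
            "replicates_per_group",
            "mean_junction_depth",
            "n_eclip_reads",
            "read_length",
            "barcode_length",
        ):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be > 0 (got {getattr(self, name)})")
        for name in (
            "frac_enhanced",
            "frac_repressed",
            "frac_minus_strand",
            "fdr_signal",
            "fdr_null",
            "frac_duplicates",
            "frac_qc_fail",
            "base_gc",
            "psi_control",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must lie in [0,1] (got {v})")
        if self.frac_enhanced + self.frac_repressed > 1.0:
            errs.append("frac_enhanced + frac_repressed must be <= 1")
        if self.exons_per_gene < 3:
            errs.append("exons_per_gene must be >= 3 so an internal cassette exon exists")
        m5 = get_motif(self.planted_motif_5p)
        if self.planted_offset_5p < len(m5) + 2:
            errs.append(
                "planted_offset_5p must leave the terminal intronic AG intact "
                f"(need >= motif length + 2 = {len(m5) + 2})"
            )
        if self.intron_length < self.planted_offset_5p + len(m5):
            errs.append(
                "intron_length smaller than planted_offset_5p + motif length"
            )
        if self.planted_motif_3p is not None:
            m3 = get_motif(self.planted_motif_3p)
            if self.planted_offset_3p < 2:
                errs.append("planted_offset_3p must be >= 2 to keep the donor GT")
            if self.planted_offset_3p + len(m3) > self.intron_length - 2:
                errs.append("3' planted motif does not fit in the intron")
        if self.intron_length < self.planted_offset_5p + len(U_TRACT):
            errs.append("intron_length too small for the planted U-rich tract")
        n_enh = int(np.floor(self.frac_enhanced * self.n_genes))
        if self.planted_sides_counts is not None:
            if len(self.planted_sides_counts) != 4 or any(
                v < 0 for v in self.planted_sides_counts
            ):
                errs.append("planted_sides_counts must be four non-negative counts")
            elif sum(self.planted_sides_counts) != n_enh:
                errs.append(
                    "planted_sides_counts must sum to the enhanced-exon count "
                    f"({n_enh})"
                )
        if errs:
            raise SimConfigError("; ".join(errs))


@dataclass
class SimTruth:
    """Ground truth emitted by the generator.

    ``exons`` has one row per gene/cassette exon (labels, reference
    coordinates of the exon trio and of every planted feature);
    ``reads`` (filled by :func:`simulate_eclip_reads`) has one row per read
    with its true crosslink position and QC/duplicate flags.
    """

    exons: pd.DataFrame
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)


def _labels(config: SimConfig) -> list[str]:
    # floor for enhanced, floor for repressed, remainder background
    n_enh = int(np.floor(config.frac_enhanced * config.n_genes))
    n_rep = int(np.floor(config.frac_repressed * config.n_genes))
    return (
        ["enhanced"] * n_enh
        + ["repressed"] * n_rep
        + ["background"] * (config.n_genes - n_enh - n_rep)
    )


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _realize(rng: np.random.Generator, motif: DegenerateMotif) -> str:
    """Sample one DNA string matching the degenerate pattern uniformly per position."""
    out = []
    for allowed in motif.positions:
        choices = sorted(allowed)
        out.append(choices[rng.integers(len(choices))])
    return "".join(out).replace("U", "T")


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame, SimTruth]:
    """Build the toy genome, its annotation and the planted truth.

    Each gene lives on its own contig and carries ``exons_per_gene`` exons;
    the middle exon is the cassette exon. Motifs and tracts are planted in
    transcript-sense coordinates, then the whole locus is
    reverse-complemented for minus-strand genes. Splice sites carry
    canonical GT/AG dinucleotides.

    Returns ``(genome, annotation, truth)`` where ``genome`` maps contig
    name to DNA sequence and ``annotation`` holds GTF-writable gene models.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _labels(config)
    m5 = get_motif(config.planted_motif_5p)
    m3 = get_motif(config.planted_motif_3p) if config.planted_motif_3p else None

    n_enh = labels.count("enhanced")
    # which side(s) each enhanced exon carries the planted motif on
    if config.planted_sides_counts is not None:
        nb, n5, n3, nn = config.planted_sides_counts
        sides = ["both"] * nb + ["5p"] * n5 + ["3p"] * n3 + ["none"] * nn
    elif m3 is not None:
        sides = ["both"] * n_enh
    else:
        sides = ["5p"] * n_enh
    if config.planted_sides_counts is not None and m3 is None:
        m3 = m5

    E, I, F = config.exon_length, config.intron_length, config.flank_length
    nx = config.exons_per_gene
    locus_len = 2 * F + nx * E + (nx - 1) * I
    cass_idx = nx // 2

    genome: dict[str, str] = {}
    gtf_rows: list[dict] = []
    truth_rows: list[dict] = []
    enh_seen = 0
    for g, label in enumerate(labels):
        gene_id = f"g{g + 1:04d}"
        contig = f"ctg{g + 1:04d}"
        seq = _random_dna(rng, locus_len, config.base_gc)
        exon_starts = [F + i * (E + I) for i in range(nx)]
        # canonical splice dinucleotides: donor gt at intron start, acceptor ag at end
        for i in range(nx - 1):
            donor = exon_starts[i] + E
            acceptor = exon_starts[i + 1]
            seq[donor : donor + 2] = np.frombuffer(b"GT", dtype="S1")
            seq[acceptor - 2 : acceptor] = np.frombuffer(b"AG", dtype="S1")

        cass_start = exon_starts[cass_idx]
        cass_end = cass_start + E
        minus = rng.random() < config.frac_minus_strand
        strand = "-" if minus else "+"

        side = "none"
        if label == "enhanced":
            side = sides[enh_seen]
            enh_seen += 1

        def plant(pos: int, text: str) -> None:
            seq[pos : pos + len(text)] = np.frombuffer(text.encode(), dtype="S1")

        motif5_sense = motif3_sense = None
        if label == "enhanced" and side in ("both", "5p"):
            motif5_sense = cass_start - config.planted_offset_5p
            plant(motif5_sense, _realize(rng, m5))
        if label == "enhanced" and side in ("both", "3p"):
            motif3_sense = cass_end + config.planted_offset_3p
            plant(motif3_sense, _realize(rng, m3))
        utract_sense = None
        if label in ("repressed", "background"):
            utract_sense = cass_start - config.planted_offset_5p
            plant(utract_sense, U_TRACT.replace("U", "T"))

        sense = seq.tobytes().decode("ascii")
        ref = reverse_complement(sense) if minus else sense
        genome[contig] = ref

        def to_ref(s: int, e: int) -> tuple[int, int]:
            return (locus_len - e, locus_len - s) if minus else (s, e)

        exon_ref = sorted(to_ref(s, s + E) for s in exon_starts)
        gtf_rows.append(
            dict(
                seqname=contig,
                source="crichsplice_sim",
                feature="gene",
                start=exon_ref[0][0] + 1,
                end=exon_ref[-1][1],
                score=".",
                strand=strand,
                frame=".",
                attribute=f'gene_id "{gene_id}";',
            )
        )
        tx = f"{gene_id}.t1"
        gtf_rows.append(
            dict(
                seqname=contig,
                source="crichsplice_sim",
                feature="transcript",
                start=exon_ref[0][0] + 1,
                end=exon_ref[-1][1],
                score=".",
                strand=strand,
                frame=".",
                attribute=f'gene_id "{gene_id}"; transcript_id "{tx}";',
            )
        )
        order = exon_ref if not minus else exon_ref[::-1]
        for num, (es, ee) in enumerate(order, start=1):
            gtf_rows.append(
                dict(
                    seqname=contig,
                    source="crichsplice_sim",
                    feature="exon",
                    start=es + 1,
                    end=ee,
                    score=".",
                    strand=strand,
                    frame=".",
                    attribute=(
                        f'gene_id "{gene_id}"; transcript_id "{tx}"; '
                        f'exon_number "{num}";'
                    ),
                )
            )

        cass_ref = to_ref(cass_start, cass_end)
        # transcript-sense neighbours of the cassette exon
        up_sense = exon_starts[cass_idx - 1]
        down_sense = exon_starts[cass_idx + 1]
        up_ref = to_ref(up_sense, up_sense + E)
        down_ref = to_ref(down_sense, down_sense + E)

        def feat_ref(s: Optional[int], length: int):
            if s is None:
                return (None, None)
            return to_ref(s, s + length)

        mo5 = feat_ref(motif5_sense, len(m5))
        mo3 = feat_ref(motif3_sense, len(m3)) if m3 is not None else (None, None)
        ut = feat_ref(utract_sense, len(U_TRACT))
        truth_rows.append(
            dict(
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                label=label,
                planted_side=side,
                locus_len=locus_len,
                cassette_start=cass_ref[0],
                cassette_end=cass_ref[1],
                upstream_start=up_ref[0],
                upstream_end=up_ref[1],
                downstream_start=down_ref[0],
                downstream_end=down_ref[1],
                motif5_start=mo5[0],
                motif5_end=mo5[1],
                motif5_offset=-config.planted_offset_5p if mo5[0] is not None else None,
                motif3_start=mo3[0],
                motif3_end=mo3[1],
                motif3_offset=config.planted_offset_3p if mo3[0] is not None else None,
                utract_start=ut[0],
                utract_end=ut[1],
                utract_sense_start=utract_sense,
            )
        )

    annotation = pd.DataFrame(gtf_rows)
    truth = SimTruth(exons=pd.DataFrame(truth_rows))
    return genome, annotation, truth


def simulate_splicing_table(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Replicate junction-count event table in the skipped-exon dialect.

    Inclusion counts are Binomial(depth, p) where p is the read-level
    inclusion probability implied by the group's inclusion level under the
    2:1 inclusion/skipping effective-length ratio, so the length-normalized
    PSI computed downstream recovers the planted value in expectation.
    Sample 1 is the knockdown condition, sample 2 the control;
    ``IncLevelDifference`` is knockdown minus control.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    inc_len, skip_len = 2, 1
    rows = []
    for _, ex in truth.exons.iterrows():
        psi_ctrl = config.psi_control
        if ex.label == "enhanced":
            psi_kd = psi_ctrl + config.delta_psi_enhanced
            fdr = config.fdr_signal
        elif ex.label == "repressed":
            psi_kd = psi_ctrl + config.delta_psi_repressed
            fdr = config.fdr_signal
        else:
            psi_kd = psi_ctrl
            fdr = config.fdr_null
        psi_kd = float(np.clip(psi_kd, 0.01, 0.99))

        def draw(psi: float) -> tuple[list[int], list[int], list[float]]:
            p_read = inc_len * psi / (inc_len * psi + skip_len * (1 - psi))
            inc = rng.binomial(config.mean_junction_depth, p_read, config.replicates_per_group)
            skip = config.mean_junction_depth - inc
            lvl = (inc / inc_len) / (inc / inc_len + skip / skip_len)
            return inc.tolist(), skip.tolist(), lvl.tolist()

        ikd, skd, lkd = draw(psi_kd)
        ict, sct, lct = draw(psi_ctrl)
        rows.append(
            dict(
                ID=f"SE_{ex.gene_id}",
                GeneID=ex.gene_id,
                chr=ex.contig,
                strand=ex.strand,
                exonStart_0base=ex.cassette_start,
                exonEnd=ex.cassette_end,
                upstreamES=ex.upstream_start,
                upstreamEE=ex.upstream_end,
                downstreamES=ex.downstream_start,
                downstreamEE=ex.downstream_end,
                IJC_SAMPLE_1=",".join(map(str, ikd)),
                SJC_SAMPLE_1=",".join(map(str, skd)),
                IJC_SAMPLE_2=",".join(map(str, ict)),
                SJC_SAMPLE_2=",".join(map(str, sct)),
                IncFormLen=inc_len,
                SkipFormLen=skip_len,
                PValue=fdr,
                FDR=fdr,
                IncLevel1=",".join(f"{v:.6f}" for v in lkd),
                IncLevel2=",".join(f"{v:.6f}" for v in lct),
                IncLevelDifference=round(float(np.mean(lkd) - np.mean(lct)), 6),
            )
        )
    return pd.DataFrame(rows)


def simulate_expression_table(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Per-gene, per-condition FPKM table; all genes are highly expressed."""
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for _, ex in truth.exons.iterrows():
        for group in ("KD", "CTRL"):
            rows.append(
                dict(
                    gene_id=ex.gene_id,
                    group=group,
                    fpkm=round(float(rng.uniform(config.fpkm_low, config.fpkm_high)), 3),
                )
            )
    return pd.DataFrame(rows)


def simulate_eclip_reads(
    config: SimConfig,
    genome: dict[str, str],
    annotation: pd.DataFrame,
    truth: SimTruth,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, pd.DataFrame]:
    """eCLIP-style reads plus crosslink and peak BED tables.

    Crosslink positions are sampled over every transcript-sense locus
    position where a read fits, with weight ``eclip_enrichment`` inside the
    planted U-rich tracts and 1 elsewhere; each read starts one nucleotide
    3' of its crosslink. Reads carry a random leading barcode; a configured
    fraction are exact PCR duplicates (same sequence, freshly drawn
    qualities) and a configured fraction get quality strings failing the
    >=50%-of-bases-over-Q30 rule. Truth rows for every read are appended to
    ``truth.reads``.

    Returns ``(reads, crosslinks, peaks)`` where ``reads`` is a list of
    ``(read_id, sequence, quality)`` FASTQ records, ``crosslinks`` has one
    0-based single-nucleotide BED row per unique molecule and ``peaks`` one
    interval per planted U-rich tract.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    L_read = config.read_length
    if L_read + config.barcode_length >= min(len(s) for s in genome.values()):
        raise SimConfigError("read_length + barcode_length exceeds transcript bounds")

    ex = truth.exons
    sense_seqs = {}
    for _, row in ex.iterrows():
        s = genome[row.contig]
        sense_seqs[row.contig] = reverse_complement(s) if row.strand == "-" else s

    # candidate crosslink positions: sense position c with read [c+1, c+1+L) in bounds
    locus_len = int(ex.locus_len.iloc[0])
    n_pos = locus_len - L_read - 1
    weights = np.ones((len(ex), n_pos))
    for i, row in enumerate(ex.itertuples()):
        if row.utract_sense_start is not None and not pd.isna(row.utract_sense_start):
            s0 = int(row.utract_sense_start)
            weights[i, s0 : min(s0 + len(U_TRACT), n_pos)] = config.eclip_enrichment
    flat_w = weights.ravel()
    flat_p = flat_w / flat_w.sum()

    n = config.n_eclip_reads
    n_fail = int(round(config.frac_qc_fail * n))
    fail = np.zeros(n, dtype=bool)
    fail[rng.choice(n, size=n_fail, replace=False)] = True

    # molecule structure: read 0 is always a fresh molecule; later reads are
    # exact PCR duplicates of an earlier molecule with prob frac_duplicates
    new = np.ones(n, dtype=bool)
    if n > 1:
        new[1:] = rng.random(n - 1) >= config.frac_duplicates
    n_new = int(new.sum())
    flat_idx = rng.choice(flat_w.size, size=n_new, p=flat_p)
    gene_idx = flat_idx // n_pos
    sense_pos = flat_idx % n_pos

    mol_of_read = np.empty(n, dtype=int)
    mol_of_read[new] = np.arange(n_new)
    created_before = np.cumsum(new) - new  # molecules existing before each read
    dup_mask = ~new
    if dup_mask.any():
        mol_of_read[dup_mask] = np.floor(
            rng.random(int(dup_mask.sum())) * created_before[dup_mask]
        ).astype(int)

    bases = np.frombuffer(b"ACGT", dtype="S1")
    barcodes = rng.choice(bases, size=(n_new, config.barcode_length))

    mol_seq: list[str] = []
    mol_contig: list[str] = []
    mol_strand: list[str] = []
    mol_refpos: list[int] = []
    xlink_rows: list[dict] = []
    contigs = ex.contig.to_numpy()
    strands = ex.strand.to_numpy()
    for j in range(n_new):
        gi = int(gene_idx[j])
        c = int(sense_pos[j])
        contig = contigs[gi]
        insert = sense_seqs[contig][c + 1 : c + 1 + L_read]
        full_seq = barcodes[j].tobytes().decode("ascii") + insert
        ref_pos = c if strands[gi] == "+" else locus_len - 1 - c
        mol_seq.append(full_seq)
        mol_contig.append(contig)
        mol_strand.append(strands[gi])
        mol_refpos.append(ref_pos)
        xlink_rows.append(
            dict(chrom=contig, start=ref_pos, end=ref_pos + 1,
                 name=f"mol{j + 1:06d}", score=0, strand=strands[gi])
        )

    # per-base qualities: Q38 background with Q20 at a fraction of positions;
    # QC-fail reads get 60% low-quality bases (fails the >=50% over-Q30 rule),
    # passing reads 10%. Duplicates share sequence but draw fresh qualities.
    m = config.barcode_length + L_read
    n_low = np.where(fail, int(np.ceil(0.6 * m)), int(np.floor(0.1 * m)))
    rank = np.argsort(rng.random((n, m)), axis=1)
    qual_arr = np.full((n, m), 38 + 33, dtype=np.uint8)
    low = rank < n_low[:, None]
    qual_arr[low] = 20 + 33

    reads: list[tuple[str, str, str]] = []
    truth_rows: list[dict] = []
    for i in range(n):
        j = int(mol_of_read[i])
        read_id = f"read{i + 1:06d}"
        reads.append((read_id, mol_seq[j], qual_arr[i].tobytes().decode("ascii")))
        truth_rows.append(
            dict(
                read_id=read_id,
                contig=mol_contig[j],
                strand=mol_strand[j],
                crosslink_pos=mol_refpos[j],
                qc_fail=bool(fail[i]),
                is_duplicate=not bool(new[i]),
            )
        )

    peaks_rows = []
    for _, row in ex.iterrows():
        if row.utract_start is None or pd.isna(row.utract_start):
            continue
        s = max(0, int(row.utract_start) - 5)
        e = min(len(genome[row.contig]), int(row.utract_end) + 5)
        peaks_rows.append(
            dict(
                chrom=row.contig,
                start=s,
                end=e,
                name=f"peak_{row.gene_id}",
                score=int(config.eclip_enrichment),
                strand=row.strand,
            )
        )

    truth.reads = pd.DataFrame(truth_rows)
    crosslinks = pd.DataFrame(xlink_rows).sort_values(["chrom", "start"], kind="stable")
    peaks = pd.DataFrame(peaks_rows).sort_values(["chrom", "start"], kind="stable")
    return reads, crosslinks.reset_index(drop=True), peaks.reset_index(drop=True)
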
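"""Skipped-exon event ingestion, PSI computation and group classification.

The classifier reproduces the filter cascade used to split a differential
cassette-exon table into four disjoint sets:

- *enhanced* (by the regulator): FDR below threshold and inclusion level
  dropping by at least ``delta_psi_min`` upon knockdown (ΔPSI = knockdown −
  control, so regulator-enhanced exons have negative ΔPSI);
- *repressed*: FDR below threshold and ΔPSI at least ``+delta_psi_min``;
- *background*: unaffected events (FDR above 50%) in highly expressed genes
  (FPKM above 5.0) whose inclusion level is neither near-always-skipped nor
  near-always-included (occupancy filter: max condition PSI above 15% and
  min condition PSI below 85%);
- *excluded*: everything else, with a reason code.

PSI is the length-normalized inclusion fraction
``(I/lI) / (I/lI + S/lS)`` with inclusion-form and skipping-form effective
lengths ``lI > lS``; with equal effective lengths it reduces to
``I/(I+S)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AS_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

#: canonical name -> rMATS 3.0.7 JC-output column name
RMATS_COLUMNS: dict[str, str] = {
    "event_id": "ID",
    "gene_id": "GeneID",
    "chrom": "chr",
    "strand": "strand",
    "exon_start": "exonStart_0base",
    "exon_end": "exonEnd",
    "upstream_es": "upstreamES",
    "upstream_ee": "upstreamEE",
    "downstream_es": "downstreamES",
    "downstream_ee": "downstreamEE",
    "inc_counts_kd": "IJC_SAMPLE_1",
    "skip_counts_kd": "SJC_SAMPLE_1",
    "inc_counts_ctrl": "IJC_SAMPLE_2",
    "skip_counts_ctrl": "SJC_SAMPLE_2",
    "inc_len": "IncFormLen",
    "skip_len": "SkipFormLen",
    "fdr": "FDR",
}


class UndefinedPSIError(ValueError):
    """Raised when PSI is requested for an event with zero informative reads."""


@dataclass(frozen=True)
class ClassifierThresholds:
    """Cutoffs of the event classifier (defaults are the standard ones)."""

    delta_psi_min: float = 0.05
    fdr_max: float = 0.05
    background_fdr_min: float = 0.50
    background_fpkm_min: float = 5.0
    psi_occupancy_low: float = 0.15
    psi_occupancy_high: float = 0.85

    def __post_init__(self) -> None:
        if not 0 < self.delta_psi_min < 1:
            raise ValueError("delta_psi_min must lie in (0, 1)")
        if self.fdr_max >= self.background_fdr_min:
            raise ValueError("fdr_max must be below background_fdr_min")


@dataclass(frozen=True)
class SpliceEvent:
    """One skipped-exon event (coordinates 0-based half-open)."""

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_es: int | None = None
    upstream_ee: int | None = None
    downstream_es: int | None = None
    downstream_ee: int | None = None


def compute_psi(I: int, S: int, lI: float, lS: float) -> float:
    """Length-normalized percent-spliced-in of one replicate.

    ``(I/lI) / (I/lI + S/lS)`` for inclusion count I, skipping count S and
    effective lengths lI, lS. Raises :class:`UndefinedPSIError` when
    ``I + S == 0`` (the event must be flagged, never silently set to 0).
    """
    if I < 0 or S < 0:
        raise ValueError("junction counts must be non-negative")
    if lI <= 0 or lS <= 0:
        raise ValueError("effective lengths must be positive")
    if I + S == 0:
        raise UndefinedPSIError("no informative reads: PSI undefined")
    inc = I / lI
    return inc / (inc + S / lS)


def inclusion_percent(included: int, excluded: int) -> float:
    """Exon inclusion as a percentage of included + excluded isoforms."""
    if included + excluded == 0:
        raise UndefinedPSIError("no isoform counts: inclusion percent undefined")
    return 100.0 * included / (included + excluded)


def _parse_counts(value) -> np.ndarray:
    if isinstance(value, str):
        return np.array([int(v) for v in value.split(",") if v != ""], dtype=float)
    return np.atleast_1d(np.asarray(value, dtype=float))


def read_rmats(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a skipped-exon differential table into canonical columns.

    ``column_map`` maps canonical names to the dialect's column names;
    defaults to the rMATS 3.0.7 JC output names. Replicate count columns
    are comma-separated lists. Effective-length columns absent from the
    dialect are assumed 1 and logged.
    """
    cmap = dict(RMATS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", comment="#")
    df = pd.DataFrame()
    for canon, col in cmap.items():
        if col in raw.columns:
            df[canon] = raw[col]
    for lcol in ("inc_len", "skip_len"):
        if lcol not in df.columns:
            logger.info("column %s absent from input dialect; assuming 1", cmap[lcol])
            df[lcol] = 1.0
    return df


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Read a (gene_id, group, fpkm) TSV."""
    return pd.read_csv(path, sep="\t", comment="#")


def attach_fpkm(events: pd.DataFrame, fpkm: pd.DataFrame) -> pd.DataFrame:
    """Attach per-gene max-over-groups FPKM as ``fpkm_max``."""
    fmax = fpkm.groupby("gene_id")["fpkm"].max().rename("fpkm_max")
    return events.merge(fmax, left_on="gene_id", right_index=True, how="left")


def add_psi(events: pd.DataFrame) -> pd.DataFrame:
    """Compute per-condition mean PSI and ΔPSI (knockdown − control).

    Replicates with zero informative reads are dropped from the mean; if a
    whole condition is uninformative the event's PSI is NaN and it will be
    excluded with reason ``undefined_psi``.
    """
    df = events.copy()
    psi_kd, psi_ctrl = [], []
    for row in df.itertuples():
        means = []
        for inc_col, skip_col in (
            ("inc_counts_kd", "skip_counts_kd"),
            ("inc_counts_ctrl", "skip_counts_ctrl"),
        ):
            inc = _parse_counts(getattr(row, inc_col))
            skip = _parse_counts(getattr(row, skip_col))
            vals = [
                compute_psi(i, s, row.inc_len, row.skip_len)
                for i, s in zip(inc, skip)
                if i + s > 0
            ]
            means.append(float(np.mean(vals)) if vals else np.nan)
        psi_kd.append(means[0])
        psi_ctrl.append(means[1])
    df["psi_kd"] = psi_kd
    df["psi_ctrl"] = psi_ctrl
    df["delta_psi"] = df["psi_kd"] - df["psi_ctrl"]
    return df


def deduplicate_events(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse events sharing cassette-exon coordinates.

    Keeps the minimum-FDR event per (chrom, strand, exon_start, exon_end);
    ties broken by larger \\|ΔPSI\\|, then lexicographic event_id. Returns
    ``(kept, dropped)``.
    """
    df = events.copy()
    df["_absd"] = df["delta_psi"].abs()
    df["_eid"] = df["event_id"].astype(str)
    order = df.sort_values(
        by=["fdr", "_absd", "_eid"], ascending=[True, False, True], kind="stable"
    )
    keys = ["chrom", "strand", "exon_start", "exon_end"]
    kept = order.drop_duplicates(subset=keys, keep="first")
    dropped = order.loc[~order.index.isin(kept.index)]
    if len(dropped):
        logger.info("deduplicate_events: dropped %d duplicate-coordinate events", len(dropped))
    return (
        kept.drop(columns=["_absd", "_eid"]).sort_index(),
        dropped.drop(columns=["_absd", "_eid"]).sort_index(),
    )


def classify_events(
    events: pd.DataFrame, thresholds: ClassifierThresholds | None = None
) -> pd.DataFrame:
    """Assign every event to enhanced / repressed / background / excluded.

    ``events`` must carry ``event_id``, coordinates, ``fdr``, ``psi_kd``,
    ``psi_ctrl``, ``delta_psi`` (see :func:`add_psi`) and ``fpkm_max``.
    The labels partition the input: duplicated-coordinate events are kept in
    the output as excluded with reason ``duplicate_exon``. Returns a frame
    with ``event_id``, ``label``, ``reason``, ``delta_psi``, ``fdr``.
    """
    th = thresholds or ClassifierThresholds()
    kept, dropped = deduplicate_events(events)

    rows = []
    for row in kept.itertuples():
        fpkm = getattr(row, "fpkm_max", np.nan)
        if np.isnan(row.psi_kd) or np.isnan(row.psi_ctrl):
            label, reason = "excluded", "undefined_psi"
        elif row.fdr < th.fdr_max and row.delta_psi <= -th.delta_psi_min:
            label, reason = "enhanced", "significant_negative_delta_psi"
        elif row.fdr < th.fdr_max and row.delta_psi >= th.delta_psi_min:
            label, reason = "repressed", "significant_positive_delta_psi"
        elif row.fdr > th.background_fdr_min:
            if not (fpkm > th.background_fpkm_min):
                label, reason = "excluded", "low_expression"
            elif not max(row.psi_kd, row.psi_ctrl) > th.psi_occupancy_low:
                label, reason = "excluded", "psi_occupancy_always_skipped"
            elif not min(row.psi_kd, row.psi_ctrl) < th.psi_occupancy_high:
                label, reason = "excluded", "psi_occupancy_always_included"
            else:
                label, reason = "background", "background_filters_passed"
        elif row.fdr < th.fdr_max:
            label, reason = "excluded", "delta_psi_below_threshold"
        else:
            label, reason = "excluded", "fdr_intermediate"
        rows.append(
            dict(
                event_id=row.event_id,
                label=label,
                reason=reason,
                delta_psi=row.delta_psi,
                fdr=row.fdr,
            )
        )
    for row in dropped.itertuples():
        rows.append(
            dict(
                event_id=row.event_id,
                label="excluded",
                reason="duplicate_exon",
                delta_psi=row.delta_psi,
                fdr=row.fdr,
            )
        )
    return pd.DataFrame(rows)


def summarize_categories(
    table: pd.DataFrame,
    fdr_max: float = 0.05,
    delta_psi_min: float = 0.05,
    type_col: str = "event_type",
    fdr_col: str = "fdr",
    delta_col: str = "delta_psi",
) -> pd.DataFrame:
    """Count significant events per alternative-splicing type plus the total.

    Significance: ``fdr < fdr_max`` and ``|ΔPSI| >= delta_psi_min``. The
    type column must take values in SE / MXE / A5SS / A3SS / RI; an unknown
    code raises, naming the offending row. An empty table yields all-zero
    counts.
    """
    bad = table.loc[~table[type_col].isin(AS_TYPES)]
    if len(bad):
        idx = bad.index[0]
        raise ValueError(
            f"unknown AS type {bad[type_col].iloc[0]!r} at row {idx}; "
            f"expected one of {AS_TYPES}"
        )
    sig = table.loc[
        (table[fdr_col] < fdr_max) & (table[delta_col].abs() >= delta_psi_min)
    ]
    counts = {t: int((sig[type_col] == t).sum()) for t in AS_TYPES}
    counts["total"] = int(sum(counts.values()))
    return pd.DataFrame(
        {"event_type": list(counts.keys()), "significant_events": list(counts.values())}
    )


def events_from_frame(df: pd.DataFrame) -> list[SpliceEvent]:
    """Materialize SpliceEvent records for window extraction."""
    out = []
    for row in df.itertuples():
        out.append(
            SpliceEvent(
                event_id=str(row.event_id),
                gene_id=str(getattr(row, "gene_id", "")),
                chrom=str(row.chrom),
                strand=str(row.strand),
                exon_start=int(row.exon_start),
                exon_end=int(row.exon_end),
                upstream_es=int(getattr(row, "upstream_es", -1)),
                upstream_ee=int(getattr(row, "upstream_ee", -1)),
                downstream_es=int(getattr(row, "downstream_es", -1)),
                downstream_ee=int(getattr(row, "downstream_ee", -1)),
            )
        )
    return out
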
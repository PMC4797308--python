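"""eCLIP read post-processing and crosslink-centered density profiles.

Pipeline order is fixed: quality filtering → exact-sequence PCR-duplicate
collapsing with barcode removal → (external alignment) → single-nucleotide
crosslink coverage over 100-nt exon flanks → per-region max normalization →
group-averaged density curves. The crosslink site is taken as the
nucleotide immediately 5' of a read's 5' end (offset −1, configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import DegenerateMotif, MotifScoreTrack, motif_score_track

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33


@dataclass(frozen=True)
class QCParams:
    """Read quality-filter parameters (Phred+33)."""

    min_quality: int = 30
    min_fraction: float = 0.5
    barcode_length: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in (0, 1]")


@dataclass
class QCReport:
    total: int = 0
    passed: int = 0

    @property
    def failed(self) -> int:
        return self.total - self.passed


def qc_filter(
    reads: Iterable[tuple[str, str, str]], params: QCParams | None = None
) -> tuple[list[tuple[str, str, str]], QCReport]:
    """Keep reads with at least ``min_fraction`` of bases over ``min_quality``.

    A base counts as high quality when its Phred score is strictly greater
    than ``min_quality``. Malformed records (length mismatch between
    sequence and quality, or empty) raise with the record index.
    """
    p = params or QCParams()
    kept: list[tuple[str, str, str]] = []
    report = QCReport()
    for i, rec in enumerate(reads):
        try:
            rid, seq, qual = rec
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed FASTQ record at index {i}") from exc
        if not seq or len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record at index {i}: {rid}")
        report.total += 1
        scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET
        if (scores > p.min_quality).sum() / len(seq) >= p.min_fraction:
            kept.append(rec)
            report.passed += 1
    return kept, report


def collapse_duplicates(
    reads: Sequence[tuple[str, str, str]], barcode_length: int
) -> list[tuple[str, str, str]]:
    """Collapse exact full-sequence duplicates, then strip the barcode.

    Reads identical over their full length (random barcode included) are
    PCR duplicates of one molecule and collapse to the first occurrence;
    reads differing anywhere, including inside the barcode, are distinct
    molecules. The leading ``barcode_length`` nucleotides are then removed
    from each survivor's sequence and quality string.
    """
    seen: dict[str, tuple[str, str, str]] = {}
    for i, (rid, seq, qual) in enumerate(reads):
        if len(seq) <= barcode_length:
            raise ValueError(
                f"read {rid} (index {i}) shorter than barcode length {barcode_length}"
            )
        if seq not in seen:
            seen[seq] = (rid, seq, qual)
    return [
        (rid, seq[barcode_length:], qual[barcode_length:])
        for rid, seq, qual in seen.values()
    ]


def crosslink_sites(
    read_starts: pd.DataFrame, offset: int = -1
) -> pd.DataFrame:
    """Shift aligned read 5'-end positions to presumed crosslink sites.

    ``read_starts`` is BED-like (chrom, start, end, name, score, strand)
    where ``start``/``end`` bracket the aligned read; the crosslink is
    placed ``offset`` nucleotides 5' of the read's 5' end in transcript
    sense (default −1: the nucleotide immediately preceding the read).
    """
    df = read_starts.copy()
    plus = df["strand"] == "+"
    pos = np.where(plus, df["start"] + offset, df["end"] - 1 - offset)
    df["start"] = pos
    df["end"] = pos + 1
    return df


@dataclass
class CrosslinkCoverage:
    """Per-nucleotide crosslink counts over one flank region, transcript sense."""

    region_id: str
    group: str
    side: str
    raw: np.ndarray
    truncated: bool = False
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = self.raw.max() if len(self.raw) else 0
        self.normalized = self.raw / m if m > 0 else np.zeros_like(self.raw, dtype=float)

    @property
    def covered(self) -> bool:
        return bool(self.raw.sum() > 0)


def crosslink_coverage(
    crosslinks: pd.DataFrame,
    flanks: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[CrosslinkCoverage]:
    """Count crosslink sites per nucleotide of each flank region.

    ``crosslinks``: BED-like single-nucleotide intervals with strand.
    ``flanks``: BED-like regions with ``name`` (= ``event_id|side``),
    ``strand``, ``event_id`` and ``side`` columns (see
    ``windows.flank_intervals``). ``groups`` maps event_id to its exon
    group label. Counts are stored in transcript sense (index 0 = most 5'
    position of the flank) and max-normalized per region; regions reaching
    past a contig end are truncated and flagged.
    """
    groups = groups or {}
    by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for (chrom, strand), sub in crosslinks.groupby(["chrom", "strand"]):
        by_chrom.setdefault(chrom, {})[strand] = np.sort(sub["start"].to_numpy())
    out = []
    for row in flanks.itertuples():
        start, end = int(row.start), int(row.end)
        truncated = False
        if start < 0:
            start, truncated = 0, True
        if contig_lengths is not None and end > contig_lengths.get(row.chrom, end):
            end, truncated = contig_lengths[row.chrom], True
            logger.warning("flank %s truncated at contig end", row.name)
        length = end - start
        counts = np.zeros(length, dtype=int)
        pos = by_chrom.get(row.chrom, {}).get(row.strand)
        if pos is not None:
            lo, hi = np.searchsorted(pos, [start, end])
            idx = pos[lo:hi] - start
            np.add.at(counts, idx, 1)
        if row.strand == "-":
            counts = counts[::-1]
        event_id = getattr(row, "event_id", str(row.name).split("|")[0])
        side = getattr(row, "side", str(row.name).split("|")[-1])
        out.append(
            CrosslinkCoverage(
                region_id=str(row.name),
                group=groups.get(event_id, ""),
                side=side,
                raw=counts,
                truncated=truncated,
            )
        )
    return out


@dataclass
class DensityProfile:
    """Positionwise mean normalized crosslink coverage for an exon group."""

    group: str
    side: str
    values: np.ndarray
    n_regions: int


def average_density(
    coverages: Sequence[CrosslinkCoverage],
    group: str | None = None,
    side: str | None = None,
) -> DensityProfile:
    """Mean normalized coverage over covered regions of one group/side.

    Regions with all-zero coverage are excluded from the average (and
    logged); an empty selection raises.
    """
    sel = [
        c
        for c in coverages
        if (group is None or c.group == group) and (side is None or c.side == side)
    ]
    dropped = sum(1 for c in sel if not c.covered)
    if dropped:
        logger.info("average_density: %d uncovered regions excluded", dropped)
    sel = [c for c in sel if c.covered]
    if not sel:
        raise ValueError(f"no covered regions for group={group!r} side={side!r}")
    lengths = {len(c.normalized) for c in sel}
    if len(lengths) > 1:
        raise ValueError("regions of unequal length cannot be averaged")
    values = np.mean([c.normalized for c in sel], axis=0)
    return DensityProfile(group or "all", side or "both", values, len(sel))


def intersect_peaks(peaks: pd.DataFrame, flanks: pd.DataFrame) -> pd.DataFrame:
    """Interval intersection of peak calls with exon flank regions.

    Both inputs are BED-like 0-based half-open frames; unsorted input is
    sorted internally (noted in the log). Output rows carry the overlap
    interval, the peak name and the flank's name/side columns.
    """
    for label, df in (("peaks", peaks), ("flanks", flanks)):
        if not df[["chrom", "start"]].equals(
            df[["chrom", "start"]].sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        ):
            logger.info("intersect_peaks: %s not sorted; sorting internally", label)
    p = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    f = flanks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    rows = []
    for chrom in sorted(set(p["chrom"]) & set(f["chrom"])):
        pc = p.loc[p["chrom"] == chrom].reset_index(drop=True)
        fc = f.loc[f["chrom"] == chrom].reset_index(drop=True)
        j0 = 0
        for pk in pc.itertuples():
            while j0 < len(fc) and fc.at[j0, "end"] <= pk.start:
                j0 += 1
            j = j0
            while j < len(fc) and fc.at[j, "start"] < pk.end:
                s = max(pk.start, fc.at[j, "start"])
                e = min(pk.end, fc.at[j, "end"])
                if s < e:
                    rows.append(
                        dict(
                            chrom=chrom,
                            start=int(s),
                            end=int(e),
                            peak=pk.name,
                            flank=fc.at[j, "name"],
                            side=fc.at[j, "side"] if "side" in fc.columns else "",
                            event_id=fc.at[j, "event_id"] if "event_id" in fc.columns else "",
                        )
                    )
                j += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak", "flank", "side", "event_id"])


def motif_score_flanks(
    flank_sequences: Mapping[str, str],
    motif: DegenerateMotif,
    window: int = 25,
) -> dict[str, MotifScoreTrack]:
    """Sliding-window motif coverage score over each flank sequence.

    Delegates to :func:`crichsplice.motifs.motif_score_track`; a 100-nt
    flank with the default 25-nt window yields 76 window starts.
    """
    return {
        rid: motif_score_track(seq, motif, window=window, region_id=rid)
        for rid, seq in flank_sequences.items()
    }
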
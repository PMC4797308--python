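"""Strand-aware sequence windows anchored on cassette-exon splice sites.

For each skipped-exon event two windows are extracted from the genome: one
centered on the splice acceptor (transcript-sense 5' boundary of the exon)
and one on the splice donor (3' boundary). Each window spans ``half_width``
nucleotides of intron and ``half_width`` of exon; minus-strand windows are
reverse-complemented so that "upstream" always means 5' in the transcript.
Sequences are reported in the RNA alphabet. Window-local offsets run
−half_width…−1 upstream of the anchor and +1…+half_width downstream, with
no position 0; the intronic acceptor-side sequence therefore ends with the
intron's terminal AG dinucleotide at offsets −2,−1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .events import SpliceEvent
from .motifs import normalize_rna
from .sim import reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchoredWindow:
    """One splice-site-anchored window in transcript sense.

    ``start``/``end`` are the reference interval (0-based half-open);
    ``sequence`` is transcript-sense RNA. ``upstream_truncated`` /
    ``downstream_truncated`` count transcript-sense bases lost to a contig
    edge (0 when the window has its full 2*half_width length).
    """

    event_id: str
    anchor: str  # "acceptor" | "donor"
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    half_width: int = 250
    upstream_truncated: int = 0
    downstream_truncated: int = 0

    @property
    def truncated(self) -> bool:
        return self.upstream_truncated > 0 or self.downstream_truncated > 0

    def offset_to_index(self, offset: int) -> int:
        """Map a window offset (−half..−1, +1..+half; no 0) to a sequence index."""
        if offset == 0 or not -self.half_width <= offset <= self.half_width:
            raise ValueError(f"offset {offset} outside window frame")
        base = offset + self.half_width if offset < 0 else offset + self.half_width - 1
        idx = base - self.upstream_truncated
        if not 0 <= idx < len(self.sequence):
            raise ValueError(f"offset {offset} truncated away in this window")
        return idx

    def index_to_offset(self, index: int) -> int:
        base = index + self.upstream_truncated
        off = base - self.half_width
        return off if off < 0 else off + 1


class GenomeAccessError(KeyError):
    """Raised when a contig named by an event is absent from the genome."""


def _get_slice(genome, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, dict):
        if chrom not in genome:
            raise GenomeAccessError(f"contig {chrom!r} not in genome")
        return genome[chrom][start:end]
    # pyfaidx.Fasta or compatible mapping of records
    try:
        rec = genome[chrom]
    except KeyError as exc:
        raise GenomeAccessError(f"contig {chrom!r} not in genome") from exc
    return str(rec[start:end])


def _contig_length(genome, chrom: str) -> int:
    if isinstance(genome, dict):
        if chrom not in genome:
            raise GenomeAccessError(f"contig {chrom!r} not in genome")
        return len(genome[chrom])
    try:
        return len(genome[chrom])
    except KeyError as exc:
        raise GenomeAccessError(f"contig {chrom!r} not in genome") from exc


def extract_window(
    genome, event: SpliceEvent, anchor: str, half_width: int = 250
) -> AnchoredWindow:
    """Extract one acceptor- or donor-anchored window for an event."""
    if event.strand not in ("+", "-"):
        raise ValueError(f"event {event.event_id}: unannotated strand {event.strand!r}")
    if anchor not in ("acceptor", "donor"):
        raise ValueError(f"unknown anchor {anchor!r}")
    # reference coordinate of the anchor boundary
    if (event.strand == "+") == (anchor == "acceptor"):
        pivot = event.exon_start
    else:
        pivot = event.exon_end
    clen = _contig_length(genome, event.chrom)
    start = pivot - half_width
    end = pivot + half_width
    left_trunc = max(0, -start)
    right_trunc = max(0, end - clen)
    start, end = max(0, start), min(clen, end)
    seq = _get_slice(genome, event.chrom, start, end).upper()
    if event.strand == "-":
        seq = reverse_complement(seq)
        up_trunc, down_trunc = right_trunc, left_trunc
    else:
        up_trunc, down_trunc = left_trunc, right_trunc
    if up_trunc or down_trunc:
        logger.warning(
            "window %s|%s truncated at contig edge (%d nt lost)",
            event.event_id,
            anchor,
            up_trunc + down_trunc,
        )
    return AnchoredWindow(
        event_id=event.event_id,
        anchor=anchor,
        chrom=event.chrom,
        strand=event.strand,
        start=start,
        end=end,
        sequence=normalize_rna(seq),
        half_width=half_width,
        upstream_truncated=up_trunc,
        downstream_truncated=down_trunc,
    )


def extract_windows(
    events: Iterable[SpliceEvent], genome, half_width: int = 250
) -> list[AnchoredWindow]:
    """Acceptor and donor windows for every event (two windows per event)."""
    out = []
    for ev in events:
        out.append(extract_window(genome, ev, "acceptor", half_width))
        out.append(extract_window(genome, ev, "donor", half_width))
    return out


def flank_intervals(
    events: Iterable[SpliceEvent], width: int = 100
) -> pd.DataFrame:
    """Purely intronic flank intervals up- and downstream of each exon.

    The 5' flank is the ``width`` intronic nucleotides immediately upstream
    of the splice acceptor; the 3' flank the ``width`` nucleotides
    immediately downstream of the donor (both transcript sense). Returned
    as a BED-like frame with ``name`` = ``event_id|side`` and a ``side``
    column in {"5p", "3p"}.
    """
    rows = []
    for ev in events:
        if ev.strand == "+":
            five = (ev.exon_start - width, ev.exon_start)
            three = (ev.exon_end, ev.exon_end + width)
        else:
            five = (ev.exon_end, ev.exon_end + width)
            three = (ev.exon_start - width, ev.exon_start)
        for side, (s, e) in (("5p", five), ("3p", three)):
            rows.append(
                dict(
                    chrom=ev.chrom,
                    start=max(0, s),
                    end=e,
                    name=f"{ev.event_id}|{side}",
                    score=0,
                    strand=ev.strand,
                    event_id=ev.event_id,
                    side=side,
                )
            )
    return pd.DataFrame(rows)


def window_fasta_records(windows: Sequence[AnchoredWindow]) -> dict[str, str]:
    """Header encodes event, anchor, strand and reference interval."""
    return {
        f"{w.event_id}|{w.anchor}|{w.strand}|{w.chrom}:{w.start}-{w.end}": w.sequence
        for w in windows
    }


def write_windows_fasta(windows: Sequence[AnchoredWindow], path: str | Path) -> None:
    from .io import write_fasta

    write_fasta(window_fasta_records(windows), path)


def read_windows_fasta(path: str | Path, half_width: int = 250) -> list[AnchoredWindow]:
    from .io import read_fasta

    out = []
    for header, seq in read_fasta(path).items():
        event_id, anchor, strand, locus = header.split("|")
        chrom, span = locus.rsplit(":", 1)
        start, end = (int(v) for v in span.split("-"))
        length = end - start
        missing = 2 * half_width - length
        # truncation side is recoverable from the anchor position
        out.append(
            AnchoredWindow(
                event_id=event_id,
                anchor=anchor,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                sequence=seq,
                half_width=half_width,
                upstream_truncated=max(0, missing) if start == 0 and strand == "+" else 0,
                downstream_truncated=max(0, missing) if not (start == 0 and strand == "+") and missing > 0 else 0,
            )
        )
    return out


def windows_bed(windows: Sequence[AnchoredWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=w.chrom,
                start=w.start,
                end=w.end,
                name=f"{w.event_id}|{w.anchor}",
                score=0,
                strand=w.strand,
            )
            for w in windows
        ]
    )
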
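"""Degenerate polypyrimidine-motif scanning and positional statistics.

This module houses the sequence-level core of the analysis: a degenerate
motif type (each position an allowed-nucleotide set, RNA alphabet), an
exhaustive overlapping scanner, splice-site-anchored positional occurrence
profiles (50-nt bins advanced 1 nt at a time over 500-nt windows), the
sliding-window motif coverage score, per-bin enrichment of a regulated exon
group against a background exon set, and the 5'/3' motif co-occurrence
contingency analysis with its continuity-corrected chi-square.

Motif patterns are written the way splicing papers print them, e.g. the
C-rich polypyrimidine consensus ``[C/U][C/U][C/U][C/U]C[U/A][C/G]CC[C/U]``.
DNA-alphabet input (T) is normalized to RNA (U) everywhere; ``N`` in a
scanned sequence never matches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: C-rich polypyrimidine consensus enriched 5' of regulator-enhanced exons.
C_RICH_PATTERN = "[C/U][C/U][C/U][C/U]C[U/A][C/G]CC[C/U]"
#: U2AF65 consensus as printed in the methods of the source analysis.
U2AF65_PATTERN = "UUUUU[C/U]U"
#: Variant U2AF65 consensus printed alongside the binding-density figures.
U2AF65_FIG_PATTERN = "UUUUU[C/U]C"


def normalize_rna(seq: str) -> str:
    """Uppercase a sequence and map DNA T to RNA U."""
    return seq.upper().replace("T", "U")


class MotifPatternError(ValueError):
    """Raised for malformed degenerate-motif patterns."""


@dataclass(frozen=True)
class DegenerateMotif:
    """Ordered positions, each a non-empty set of allowed RNA nucleotides."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise MotifPatternError("motif must have at least one position")
        for i, allowed in enumerate(self.positions):
            if not allowed or not allowed <= RNA_ALPHABET:
                raise MotifPatternError(
                    f"position {i}: allowed set {sorted(allowed)} not a "
                    f"non-empty subset of {{A,C,G,U}}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_pattern(cls, pattern: str, name: str | None = None) -> "DegenerateMotif":
        """Parse bracket syntax like ``[C/U][C/U]C[U/A]CC`` (T accepted for U)."""
        positions: list[frozenset[str]] = []
        i = 0
        pat = pattern.replace(" ", "")
        while i < len(pat):
            ch = pat[i]
            if ch == "[":
                j = pat.find("]", i)
                if j < 0:
                    raise MotifPatternError(f"unclosed '[' in pattern {pattern!r}")
                letters = pat[i + 1 : j].split("/")
                positions.append(frozenset(normalize_rna(c) for c in letters))
                i = j + 1
            else:
                positions.append(frozenset(normalize_rna(ch)))
                i += 1
        return cls(name or pattern, tuple(positions))

    @property
    def pattern(self) -> str:
        """Render back to bracket syntax."""
        out = []
        for allowed in self.positions:
            if len(allowed) == 1:
                out.append(next(iter(allowed)))
            else:
                out.append("[" + "/".join(sorted(allowed)) + "]")
        return "".join(out)

    def matches_at(self, seq: str, start: int) -> bool:
        if start < 0 or start + len(self) > len(seq):
            return False
        return all(seq[start + k] in allowed for k, allowed in enumerate(self.positions))


#: Named presets for the two consensus patterns used throughout the analysis.
MOTIF_PRESETS: dict[str, DegenerateMotif] = {
    "crich": DegenerateMotif.from_pattern(C_RICH_PATTERN, "crich"),
    "u2af65": DegenerateMotif.from_pattern(U2AF65_PATTERN, "u2af65"),
    "u2af65_fig6": DegenerateMotif.from_pattern(U2AF65_FIG_PATTERN, "u2af65_fig6"),
}


def get_motif(motif: str | DegenerateMotif) -> DegenerateMotif:
    """Resolve a preset name or bracket pattern to a DegenerateMotif."""
    if isinstance(motif, DegenerateMotif):
        return motif
    if motif in MOTIF_PRESETS:
        return MOTIF_PRESETS[motif]
    return DegenerateMotif.from_pattern(motif)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, in window-local coordinates."""

    window_id: str
    start: int
    length: int


def scan_motif(sequence: str, motif: DegenerateMotif, window_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) motif start positions in a sequence.

    The sequence may be DNA or RNA alphabet; ``N`` never matches. A motif
    longer than the sequence yields an empty list. Hits are returned in
    ascending start order.
    """
    seq = normalize_rna(sequence)
    m = len(motif)
    n = len(seq)
    if m > n:
        return []
    # membership mask per motif position, vectorised over sequence offsets
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    ok = np.ones(n - m + 1, dtype=bool)
    for k, allowed in enumerate(motif.positions):
        allowed_bytes = np.array(sorted(a.encode() for a in allowed), dtype="S1")
        ok &= np.isin(arr[k : k + n - m + 1], allowed_bytes)
    return [MotifHit(window_id, int(s), m) for s in np.nonzero(ok)[0]]


@dataclass
class PositionalProfile:
    """Binned positional occurrence of a motif over a group of windows.

    ``counts[b]`` is the number of hit starts falling in ``[b, b+bin_width)``
    summed over all windows of the group; ``windows_with_hit[b]`` is the
    number of windows contributing at least one hit start to that bin (the
    quantity used by the per-bin presence/absence enrichment test).
    """

    group: str
    anchor: str
    window_length: int
    n_windows: int
    bin_width: int = 50
    step: int = 1
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    windows_with_hit: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(0, self.window_length - self.bin_width + 1, self.step)

    @property
    def frequency(self) -> np.ndarray:
        return self.counts / self.n_windows


def positional_profile(
    hits_per_window: Mapping[str, Sequence[MotifHit]] | Sequence[Sequence[MotifHit]],
    group: str,
    window_length: int,
    anchor: str = "acceptor",
    bin_width: int = 50,
    step: int = 1,
) -> PositionalProfile:
    """Bin motif hit starts over a group of equal-length windows.

    A hit counts in every bin whose interval ``[b, b+bin_width)`` contains
    its start offset. Raises ``ValueError`` on an empty group.
    """
    if hasattr(hits_per_window, "values"):
        per_window = list(hits_per_window.values())  # type: ignore[union-attr]
    else:
        per_window = list(hits_per_window)
    if not per_window:
        raise ValueError("positional_profile: empty window group")
    bin_starts = np.arange(0, window_length - bin_width + 1, step)
    n_bins = len(bin_starts)
    counts = np.zeros(n_bins, dtype=int)
    with_hit = np.zeros(n_bins, dtype=int)
    for hits in per_window:
        window_bins = np.zeros(n_bins, dtype=int)
        for h in hits:
            # bins with b <= start < b + bin_width
            lo = max(0, h.start - bin_width + 1)
            hi = min(n_bins - 1, h.start)
            if lo <= hi:
                window_bins[lo : hi + 1] += 1
        counts += window_bins
        with_hit += window_bins > 0
    return PositionalProfile(
        group=group,
        anchor=anchor,
        window_length=window_length,
        n_windows=len(per_window),
        bin_width=bin_width,
        step=step,
        counts=counts,
        windows_with_hit=with_hit,
    )


@dataclass
class MotifScoreTrack:
    """Sliding-window motif coverage score over one region.

    At each window start the score is the number of unique nucleotides
    covered by any motif instance inside the window, divided by the window
    length, so it lies in [0, 1] and reaches 1 only when instances tile the
    window completely.
    """

    region_id: str
    window: int
    scores: np.ndarray
    short_region: bool = False


def motif_score_track(
    sequence: str,
    motif: DegenerateMotif,
    window: int = 25,
    region_id: str = "",
) -> MotifScoreTrack:
    """Motif coverage score in a sliding window advanced 1 nt at a time.

    A region shorter than the window yields a single score computed over the
    whole region with its true length as denominator, flagged as
    ``short_region``.
    """
    seq = normalize_rna(sequence)
    n = len(seq)
    covered = np.zeros(n, dtype=bool)
    for h in scan_motif(seq, motif, region_id):
        covered[h.start : h.start + h.length] = True
    if n < window:
        logger.warning("region %s (%d nt) shorter than score window %d", region_id, n, window)
        return MotifScoreTrack(region_id, window, np.array([covered.sum() / n]), True)
    kernel = np.ones(window, dtype=int)
    cov_counts = np.convolve(covered.astype(int), kernel, mode="valid")
    return MotifScoreTrack(region_id, window, cov_counts / window, False)


def enrichment_vs_background(profile_group: PositionalProfile, profile_bg: PositionalProfile):
    """Per-bin enrichment of a group profile against the background profile.

    For each bin a 2x2 Fisher exact test compares windows with >=1 hit start
    in the bin versus without, group versus background; p-values are
    Benjamini-Hochberg adjusted across bins. Returns a pandas DataFrame with
    ``bin_start``, per-set frequencies, ``log2_ratio`` and ``q_value``.
    Frequencies of zero in both sets give a log-ratio of 0; a zero on one
    side gives +/-inf.
    """
    import pandas as pd

    if profile_group.anchor != profile_bg.anchor:
        raise ValueError("profiles anchored on different splice sites")
    if (
        profile_group.window_length != profile_bg.window_length
        or profile_group.bin_width != profile_bg.bin_width
        or profile_group.step != profile_bg.step
    ):
        raise ValueError("profiles have mismatched bin geometry")
    if profile_group.n_windows == 0 or profile_bg.n_windows == 0:
        raise ValueError("zero-size group")

    n_g, n_b = profile_group.n_windows, profile_bg.n_windows
    k_g = profile_group.windows_with_hit
    k_b = profile_bg.windows_with_hit
    pvals = np.array(
        [
            stats.fisher_exact([[kg, n_g - kg], [kb, n_b - kb]])[1]
            for kg, kb in zip(k_g, k_b)
        ]
    )
    qvals = stats.false_discovery_control(pvals, method="bh")
    f_g = profile_group.frequency
    f_b = profile_bg.frequency
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(f_g / f_b)
    ratio[(f_g == 0) & (f_b == 0)] = 0.0
    return pd.DataFrame(
        {
            "bin_start": profile_group.bin_starts,
            "freq_group": f_g,
            "freq_background": f_b,
            "log2_ratio": ratio,
            "p_value": pvals,
            "q_value": qvals,
        }
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of motif presence 5' and 3' of an exon set.

    ``a``: present both sides; ``b``: 5' only; ``c``: 3' only; ``d``: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def cooccurrence_table(
    event_ids: Iterable[str],
    hits_acceptor: Mapping[str, Sequence[MotifHit]],
    hits_donor: Mapping[str, Sequence[MotifHit]],
    half_width: int = 250,
) -> ContingencyTable2x2:
    """Classify each exon by intronic motif presence 5' and 3' of it.

    Presence on the 5' side means >=1 hit starting in the intronic half of
    the acceptor window (offsets -half_width..-1, i.e. indices
    ``[0, half_width)``); on the 3' side, >=1 hit starting in the intronic
    half of the donor window (offsets +1..+half_width, indices
    ``[half_width, 2*half_width)``). Exons missing either window are
    excluded and logged.
    """
    a = b = c = d = 0
    for ev in event_ids:
        if ev not in hits_acceptor or ev not in hits_donor:
            logger.warning("cooccurrence_table: event %s missing a window; excluded", ev)
            continue
        p5 = any(h.start < half_width for h in hits_acceptor[ev])
        p3 = any(h.start >= half_width for h in hits_donor[ev])
        if p5 and p3:
            a += 1
        elif p5:
            b += 1
        elif p3:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = True
) -> tuple[float, float]:
    """Chi-square test of independence on a 2x2 table, 1 degree of freedom.

    Uses the closed form ``N(|ad-bc| - N/2)^2 / (r1 r2 c1 c2)`` with the
    Yates continuity correction on by default (the N/2 term, clamped at
    zero); without correction the N/2 term is dropped. Returns
    ``(statistic, p_value)`` with p from the upper tail of chi-square(1).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(
            "a marginal total is zero; the chi-square approximation is "
            "undefined here - use Fisher's exact test"
        )
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(0.0, diff - n / 2.0)
    statistic = n * diff**2 / (r1 * r2 * c1 * c2)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p_value


def derived_motif_fractions(table: ContingencyTable2x2) -> dict[str, dict[str, float]]:
    """Summary counts and percentages read off the co-occurrence table.

    Returns, for the exon group the table was built from:

    - ``either_side``: motif on at least one side (a+b+c), % of the group;
    - ``upstream``: motif 5' of the exon (a+b), % of the either-side set;
    - ``upstream_only``: motif restricted to the 5' side (b), % of the group;
    - ``downstream_only``: motif restricted to the 3' side (c), % of the
      either-side set.

    Percentage bases differ on purpose: they match how such tables are
    conventionally reported (side-restricted fractions of motif-bearing
    exons vs. of the whole group). Percentages are rounded to the nearest
    integer for reporting.
    """
    if table.total == 0:
        raise ValueError("empty table: percentages undefined")
    either = table.a + table.b + table.c
    upstream = table.a + table.b
    out = {
        "either_side": {"count": either, "percent": round(100 * either / table.total)},
        "upstream": {
            "count": upstream,
            "percent": round(100 * upstream / either) if either else math.nan,
        },
        "upstream_only": {
            "count": table.b,
            "percent": round(100 * table.b / table.total),
        },
        "downstream_only": {
            "count": table.c,
            "percent": round(100 * table.c / either) if either else math.nan,
        },
    }
    return out
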
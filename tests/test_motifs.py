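"""Motif scanning, positional profiles, score tracks and contingency stats."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from crichsplice.motifs import (
    C_RICH_PATTERN,
    MOTIF_PRESETS,
    ContingencyTable2x2,
    DegenerateMotif,
    MotifHit,
    MotifPatternError,
    chi_square_2x2,
    cooccurrence_table,
    derived_motif_fractions,
    enrichment_vs_background,
    motif_score_track,
    positional_profile,
    scan_motif,
)
from conftest import rand_seq


# ---------------------------------------------------------------- pattern type


def test_pattern_parse_roundtrip():
    m = DegenerateMotif.from_pattern(C_RICH_PATTERN, "crich")
    assert len(m) == 10
    assert m.positions[4] == frozenset("C")
    assert m.positions[0] == frozenset("CU")
    assert DegenerateMotif.from_pattern(m.pattern).positions == m.positions


def test_pattern_accepts_dna_alphabet():
    m = DegenerateMotif.from_pattern("TTTTT[C/T]T")
    assert m.pattern == MOTIF_PRESETS["u2af65"].pattern


@pytest.mark.parametrize("bad", ["", "[C/U", "[X]C", "CN"])
def test_pattern_rejects_malformed(bad):
    with pytest.raises(MotifPatternError):
        DegenerateMotif.from_pattern(bad)


def test_u2af65_presets_differ_in_last_position():
    # two printed variants of the same consensus are kept distinct on purpose
    a, b = MOTIF_PRESETS["u2af65"], MOTIF_PRESETS["u2af65_fig6"]
    assert a.positions[:-1] == b.positions[:-1]
    assert a.positions[-1] == frozenset("U") and b.positions[-1] == frozenset("C")


# ------------------------------------------------------------------- scanning


@pytest.mark.parametrize(
    "seq,motif,starts",
    [
        ("CCCCCUCCCC", "crich", [0]),
        ("AAAAAAAAAAAA", "crich", []),
        ("UUUUUCU", "u2af65", [0]),
        ("TTTTTCT", "u2af65", [0]),  # DNA input normalized
        ("UUUUUNU", "u2af65", []),  # N never matches
        ("CCC", "crich", []),  # motif longer than window
    ],
)
def test_scan_examples(seq, motif, starts):
    hits = scan_motif(seq, MOTIF_PRESETS[motif])
    assert [h.start for h in hits] == starts


def brute_force_scan(seq, motif):
    seq = seq.upper().replace("T", "U")
    out = []
    for s in range(len(seq) - len(motif) + 1):
        if all(seq[s + k] in allowed for k, allowed in enumerate(motif.positions)):
            out.append(s)
    return out


def test_scan_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    motifs = list(MOTIF_PRESETS.values()) + [
        DegenerateMotif.from_pattern("[C/U]C[A/G/U]"),
        DegenerateMotif.from_pattern("UU[C/U]"),
    ]
    for i in range(1000):
        # pyrimidine-biased alphabet so hits actually occur
        seq = rand_seq(rng, int(rng.integers(5, 60)), "ACGUUCCUN")
        m = motifs[i % len(motifs)]
        assert [h.start for h in scan_motif(seq, m)] == brute_force_scan(seq, m)


def test_scan_reports_overlapping_hits_in_order():
    hits = scan_motif("UUUUUUUU", MOTIF_PRESETS["u2af65"])
    assert [h.start for h in hits] == [0, 1]


# ------------------------------------------------------------------- profiles


def test_profile_single_hit_boxcar():
    hits = {"w1": [MotifHit("w1", 60, 10)]}
    p = positional_profile(hits, "g", window_length=500)
    # bins [b, b+50) containing start 60: b in 11..60
    expected = np.zeros(451, dtype=int)
    expected[11:61] = 1
    assert np.array_equal(p.counts, expected)
    assert np.array_equal(p.windows_with_hit, expected)
    assert p.frequency.max() == 1.0


def test_profile_no_hits_is_zero():
    p = positional_profile({"w1": [], "w2": []}, "g", window_length=500)
    assert p.counts.sum() == 0 and p.n_windows == 2


def test_profile_empty_group_raises():
    with pytest.raises(ValueError):
        positional_profile({}, "g", window_length=500)


def brute_force_profile(hit_starts, window_length, bin_width):
    bins = []
    for b in range(window_length - bin_width + 1):
        bins.append(sum(1 for s in hit_starts for _ in [0] if b <= s < b + bin_width))
    return np.array(bins)


def test_profile_matches_enumeration_oracle():
    rng = np.random.default_rng(5)
    L, bw = 200, 50
    for _ in range(200):
        n_windows = int(rng.integers(1, 4))
        hits = {}
        all_starts = []
        for w in range(n_windows):
            starts = sorted(rng.integers(0, L - 5, size=rng.integers(0, 8)).tolist())
            hits[f"w{w}"] = [MotifHit(f"w{w}", s, 5) for s in starts]
            all_starts.extend(starts)
        p = positional_profile(hits, "g", window_length=L, bin_width=bw)
        assert np.array_equal(p.counts, brute_force_profile(all_starts, L, bw))


def test_profile_total_counts_interior_hits():
    # one interior hit contributes to exactly bin_width bins
    p = positional_profile({"w": [MotifHit("w", 250, 10)]}, "g", window_length=500)
    assert p.counts.sum() == 50


# ---------------------------------------------------------------- score track


def coverage_union_score(seq, motif, window):
    seq = seq.upper().replace("T", "U")
    covered = set()
    for s in brute_force_scan(seq, motif):
        covered.update(range(s, s + len(motif)))
    return [
        len(covered & set(range(w, w + window))) / window
        for w in range(len(seq) - window + 1)
    ]


def test_score_single_hit():
    seq = "A" * 9 + "UUUUUCU" + "A" * 9  # one 7-mer inside a 25-nt region
    tr = motif_score_track(seq, MOTIF_PRESETS["u2af65"], window=25)
    assert tr.scores.shape == (1,)
    assert tr.scores[0] == pytest.approx(7 / 25)


def test_score_two_overlapping_hits():
    seq = "A" * 9 + "UUUUUUUU" + "A" * 8  # hits at offsets 9 and 10, union 8 nt
    tr = motif_score_track(seq, MOTIF_PRESETS["u2af65"], window=25)
    assert tr.scores[0] == pytest.approx(8 / 25)


def test_score_hit_free_window_is_zero():
    tr = motif_score_track("A" * 40, MOTIF_PRESETS["u2af65"], window=25)
    assert np.all(tr.scores == 0)


def test_score_fully_tiled_sequence_is_one():
    tr = motif_score_track("U" * 60, DegenerateMotif.from_pattern("U"), window=25)
    assert np.all(tr.scores == 1.0)


def test_score_short_region_flagged():
    tr = motif_score_track("UUUUUCUAAA", MOTIF_PRESETS["u2af65"], window=25)
    assert tr.short_region and tr.scores == pytest.approx([7 / 10])


def test_score_matches_coverage_union_oracle():
    rng = np.random.default_rng(17)
    for _ in range(300):
        seq = rand_seq(rng, int(rng.integers(25, 120)), "ACGUUCU")
        tr = motif_score_track(seq, MOTIF_PRESETS["u2af65"], window=25)
        assert tr.scores == pytest.approx(coverage_union_score(seq, MOTIF_PRESETS["u2af65"], 25))
        assert np.all((tr.scores >= 0) & (tr.scores <= 1))


# ------------------------------------------------------------------ enrichment


def _profile_from_starts(starts_per_window, L=120):
    hits = {
        f"w{i}": [MotifHit(f"w{i}", s, 5) for s in starts]
        for i, starts in enumerate(starts_per_window)
    }
    return positional_profile(hits, "g", window_length=L)


def test_enrichment_identity_is_null():
    p = _profile_from_starts([[10, 40], [60], []])
    out = enrichment_vs_background(p, p)
    assert np.all(out["log2_ratio"] == 0)
    assert np.all(out["q_value"] > 0.99)


def test_enrichment_swap_negates_log_ratio():
    g = _profile_from_starts([[10], [10, 50], []])
    b = _profile_from_starts([[80], [], [], []])
    fwd = enrichment_vs_background(g, b)
    rev = enrichment_vs_background(b, g)
    assert np.allclose(fwd["log2_ratio"], -rev["log2_ratio"], equal_nan=True)
    assert np.allclose(fwd["p_value"], rev["p_value"])


def test_enrichment_geometry_mismatch_raises():
    g = _profile_from_starts([[10]])
    b = positional_profile({"w": []}, "bg", window_length=200)
    with pytest.raises(ValueError):
        enrichment_vs_background(g, b)


# ------------------------------------------------------------ contingency part


def test_chi_square_corrected_vs_uncorrected():
    table = ContingencyTable2x2(311, 333, 42, 63)
    stat, p = chi_square_2x2(table, continuity_correction=True)
    stat_u, _ = chi_square_2x2(table, continuity_correction=False)
    assert round(stat, 2) == 2.17
    assert round(p, 3) == 0.141
    assert round(stat_u, 2) == 2.49
    assert stat_u > stat


def test_chi_square_perfect_independence_is_zero():
    stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
    assert stat == 0.0 and p == 1.0


def test_chi_square_zero_marginal_raises():
    with pytest.raises(ValueError, match="exact"):
        chi_square_2x2(ContingencyTable2x2(5, 5, 0, 0))


def test_chi_square_matches_scipy_oracle():
    rng = np.random.default_rng(23)
    checked = 0
    while checked < 1000:
        a, b, c, d = rng.integers(0, 40, size=4)
        t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        for corr in (True, False):
            stat, p = chi_square_2x2(t, continuity_correction=corr)
            ref_stat, ref_p, _, _ = chi2_contingency(t.as_array(), correction=corr)
            assert stat == pytest.approx(ref_stat, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)
        stat_c, _ = chi_square_2x2(t, True)
        stat_u, _ = chi_square_2x2(t, False)
        assert stat_c <= stat_u + 1e-12
        checked += 1


def test_cooccurrence_classification():
    h5 = {
        "both": [MotifHit("both|acceptor", 100, 10)],
        "five": [MotifHit("five|acceptor", 240, 10)],
        "three": [MotifHit("three|acceptor", 300, 10)],  # exonic side: no 5' presence
        "none": [],
    }
    h3 = {
        "both": [MotifHit("both|donor", 260, 10)],
        "five": [MotifHit("five|donor", 100, 10)],  # exonic side of donor window
        "three": [MotifHit("three|donor", 450, 10)],
        "none": [],
    }
    t = cooccurrence_table(["both", "five", "three", "none"], h5, h3)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_cooccurrence_missing_window_excluded():
    t = cooccurrence_table(["ev1", "ev2"], {"ev1": []}, {"ev1": []})
    assert t.total == 1 and t.d == 1


def test_cooccurrence_empty_group():
    t = cooccurrence_table([], {}, {})
    assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)


def test_cooccurrence_recovers_planted_pattern():
    """A truth-planted per-side pattern is recovered exactly by scanning."""
    from crichsplice.events import SpliceEvent
    from crichsplice.sim import SimConfig, simulate_genome
    from crichsplice.windows import extract_windows

    cfg = SimConfig(n_genes=75, frac_enhanced=1.0, frac_repressed=0.0,
                    planted_sides_counts=(31, 33, 4, 7), base_gc=0.2, seed=1)
    genome, _, truth = simulate_genome(cfg)
    events = [
        SpliceEvent(r.gene_id, r.gene_id, r.contig, r.strand,
                    int(r.cassette_start), int(r.cassette_end))
        for r in truth.exons.itertuples()
    ]
    wins = extract_windows(events, genome)
    m = MOTIF_PRESETS["crich"]
    h5 = {w.event_id: scan_motif(w.sequence, m, w.event_id)
          for w in wins if w.anchor == "acceptor"}
    h3 = {w.event_id: scan_motif(w.sequence, m, w.event_id)
          for w in wins if w.anchor == "donor"}
    t = cooccurrence_table([e.event_id for e in events], h5, h3)
    assert (t.a, t.b, t.c, t.d) == (31, 33, 4, 7)


def test_fractions_reference_table():
    out = derived_motif_fractions(ContingencyTable2x2(311, 333, 42, 63))
    assert out["either_side"] == {"count": 686, "percent": 92}
    assert out["upstream"] == {"count": 644, "percent": 94}
    assert out["upstream_only"]["count"] == 333
    assert out["downstream_only"] == {"count": 42, "percent": 6}


def test_fractions_degenerate_tables():
    out = derived_motif_fractions(ContingencyTable2x2(1, 0, 0, 0))
    assert out["either_side"] == {"count": 1, "percent": 100}
    with pytest.raises(ValueError):
        derived_motif_fractions(ContingencyTable2x2(0, 0, 0, 0))
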
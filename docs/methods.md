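# Methods

This note documents the models, conventions and design choices behind
`crichsplice`, in the order the pipeline runs them.

## Event classification

**PSI.** Percent spliced in per replicate is the length-normalized inclusion
fraction ψ = (I/lI)/((I/lI) + (S/lS)), where I and S are junction read
counts supporting the inclusion and skipping forms and lI, lS the effective
lengths of those forms (the inclusion form spans two junctions, so lI > lS;
the package's synthetic tables use lI = 2, lS = 1). When an input dialect
carries no effective-length columns, lI = lS = 1 is assumed and logged, in
which case ψ reduces to I/(I+S). A replicate with I + S = 0 has undefined
PSI: it is dropped from the condition mean, and an event whose whole
condition is uninformative is *excluded* with reason `undefined_psi` —
never silently scored as 0. Condition-level PSI is the arithmetic mean over
replicates, and ΔPSI = ψ(knockdown) − ψ(control). Under this sign
convention an exon *enhanced* by the regulator loses inclusion upon
depletion, i.e. has negative ΔPSI; this is stated explicitly here because
the direction is otherwise easy to invert.

**Filters.** Defaults: |ΔPSI| ≥ 0.05 and FDR < 0.05 for the regulated sets;
FDR > 0.50, FPKM > 5.0 and the PSI occupancy filter (max condition ψ >
0.15, min condition ψ < 0.85) for the background set. The occupancy filter
is applied to the background set only — it exists to remove exons that are
almost always skipped or almost always included and would otherwise dilute
the enrichment control — not to the regulated sets, whose membership is
already conditioned on a significant change. The differential-splicing FDR
itself is read from the input table: it is the output of the upstream
differential-splicing tool, whose statistical model this package
deliberately does not re-implement.

**Duplicate events.** A cassette exon can appear in several skipped-exon
events (different flanking-exon pairs). Events sharing cassette-exon
coordinates are collapsed to the minimum-FDR event, ties broken by larger
|ΔPSI| and then lexicographic event id; the dropped events remain in the
output labelled `excluded`/`duplicate_exon` so that the four labels always
partition the input.

## Splice-site windows

Windows are anchored on the transcript-sense boundaries of the cassette
exon: the acceptor anchor is the exon's 5′ boundary, the donor anchor its
3′ boundary. Each window spans `half_width` (default 250) nt of intron and
the same of exon; exonic sequence is retained so exonic depletion of a
motif is observable. Minus-strand windows are reverse-complemented, so
"upstream" always means 5′ in the transcript, and all sequences are
reported in the RNA alphabet. Window offsets run −250…−1 and +1…+250 with
no position 0; the intronic acceptor side therefore ends with the intron's
terminal AG at offsets −2,−1 (the splice-site dinucleotides are retained in
the windows rather than masked). Internally all coordinates are 0-based
half-open; GTF is converted from 1-based inclusive at the boundary. Windows
truncated by a contig edge are flagged and excluded from group profiles,
which require equal window lengths.

## Motif scanning and positional profiles

Degenerate motifs are ordered allowed-nucleotide sets parsed from bracket
syntax (`[C/U][C/U]…`); DNA input (T) is normalized to U and `N` never
matches. Scanning is exhaustive: every offset is tested and overlapping
hits are all reported, with no greedy masking. Three presets ship with the
package: the C-rich consensus `[C/U][C/U][C/U][C/U]C[U/A][C/G]CC[C/U]` and
two printed variants of the U2AF65 consensus, `UUUUU[C/U]U` (`u2af65`, the
default) and `UUUUU[C/U]C` (`u2af65_fig6`). The variants circulate side by
side in the literature; both are kept rather than silently reconciled.

Positional profiles bin hits by **start position**: a hit counts in every
50-nt bin whose interval contains its start (the simplest reading of
"occurrence within each bin", and the convention the test oracles encode).
Bins advance 1 nt, so a 500-nt window yields 451 bins. Per-bin group
frequency is total hit count divided by group size; the profile also tracks,
per bin, how many windows contribute at least one hit, which is the
quantity the enrichment test uses.

**Per-bin enrichment.** For each bin, a 2×2 Fisher exact test compares
windows with versus without a hit start in the bin, group versus
background, with Benjamini–Hochberg adjustment across bins. The test choice
is a design decision of this package (recorded in output metadata): window
presence/absence is robust to a single window contributing many overlapping
hits, which count-based tests would overweight. Log2 frequency ratios are
reported alongside; a bin empty in both sets has ratio 0, a bin empty in
one set ±∞.

## Motif score

For a region and motif, the union of nucleotides covered by any motif
instance is intersected with a sliding window (default 25 nt, step 1):
score = |covered ∩ window| / |window| ∈ [0, 1], reaching 1 only when
instances tile the window. A region shorter than the window gets a single
score with its true length as denominator, flagged. A 100-nt flank with the
25-nt window yields 76 window starts.

## Co-occurrence statistics

For the enhanced exon set, motif presence is assessed separately in the
intronic half of the acceptor window (offsets −250…−1) and of the donor
window (+1…+250), presence meaning at least one hit start in that range.
The resulting 2×2 table (both / 5′ only / 3′ only / neither) is tested for
independence with the chi-square statistic at 1 d.f., **continuity
correction on by default**: χ² = N(max(|ad−bc| − N/2, 0))² / (r₁r₂c₁c₂).
Both corrected and uncorrected forms are implemented in closed form and
cross-checked against `scipy.stats.chi2_contingency` in the tests; on the
reference table (311, 333, 42, 63) they give 2.17 and 2.49 respectively —
the corrected value is the one matching the published analysis, which fixed
the default. A zero marginal raises with a pointer to Fisher's exact test.
Derived flank fractions report counts with percentages on mixed bases,
matching reporting convention: either-side and upstream-only as a
percentage of the whole group, upstream and downstream-only as a percentage
of the motif-bearing (either-side) subset.

## eCLIP processing

Stage order is fixed and each stage only removes reads: QC → duplicate
collapse → (external alignment, consumed as BED) → crosslink coverage. QC
keeps a read when at least 50% of its bases exceed Q30 (strictly greater,
Phred+33). PCR duplicates are reads identical over their **full** sequence,
random barcode included — identical inserts with different barcodes are
distinct molecules; survivors then lose their leading `barcode_length` nt.
Barcode length is not derivable from the data and is a required parameter
(synthetic default 10).

The crosslink site is the nucleotide immediately 5′ of the read's 5′ end
(offset −1, configurable); coverage counts that single nucleotide per read
rather than the full read span — "centering at the crosslink site" is
interpreted as single-nucleotide assignment, which avoids read-length smear
in the density curves. Coverage over each 100-nt flank is max-normalized
per region (so every covered region peaks at exactly 1, making the curves
comparable across expression levels; normalization is idempotent), regions
with zero coverage are dropped from averaging, and the group density curve
is the positionwise mean over covered regions in transcript sense.
Peak–flank intersection is a sorted sweep over 0-based half-open intervals,
validated against a brute-force all-pairs oracle.

## Synthetic data generator

The generator emulates the study design the analysis assumes, with defaults
chosen as the regime the method is meant for:

- 200 genes on separate contigs, 3 exons each (120 nt) with 600-nt introns
  and 300-nt terminal flanks, ~30% on the minus strand to exercise strand
  handling; splice sites carry canonical GT/AG dinucleotides; background
  base composition at 45% GC.
- Label partition by the floor rule — ⌊frac_enhanced·n⌋ enhanced (default
  15%), ⌊frac_repressed·n⌋ repressed (5%), remainder background — mirroring
  the observed predominance of enhanced targets.
- Enhanced exons get a realization of the C-rich consensus (sampled
  uniformly per position from the allowed sets) planted 30 nt upstream of
  the acceptor (offsets −30…−21); repressed and background exons get the
  U-rich tract `UUUUUCUUUUUCUUUU` at the same location. An optional
  per-side planting pattern lets a caller construct arbitrary 2×2
  co-occurrence structure.
- Junction counts are Binomial(depth = 1000, p) per replicate (3 per
  condition), with p the read-level inclusion probability implied by the
  target PSI under the 2:1 effective-length ratio, so downstream
  length-normalized PSI recovers the planted value (control ψ = 0.5,
  planted ΔPSI = ∓0.3). FDR columns are 0.01 for regulated and 0.9 for
  background exons; FPKM is uniform on [10, 100], above the background
  cutoff.
- eCLIP reads (default 20 000 × 40 nt + 10-nt barcode) start one nucleotide
  3′ of crosslink positions sampled with 10× weight inside the planted
  U-rich tracts; 20% of reads are exact PCR duplicates (fresh quality
  strings — qualities are per-cluster, not per-molecule) and an exact 10%
  of reads receive quality strings failing the Q30 rule.

Everything flows from one seeded generator; identical configurations give
byte-identical output files. What the generator does **not** emulate:
realistic splice-site strength variation, intron-length and GC
heterogeneity, motif realizations arising by chance with realistic
genome-scale frequency, expression-dependent junction depth, alignment
error, or eCLIP background structure (crosslink sequence bias, transcript
abundance). Passing tests therefore demonstrate that the implementation
recovers planted structure under its own assumptions — not that the
biological effect sizes would be detectable in any given real dataset.

## Problem sizes and numerical notes

The bundled test suite and the acceptance script run the full pipeline at
200 genes with 20 000 eCLIP reads, a size at which every recovery property
(≥99% label recovery, profile peak inside the planted interval, density
peak inside the planted tract) holds with wide margin across seeds.
Fisher p-values come from `scipy.stats.fisher_exact`, BH adjustment from
`scipy.stats.false_discovery_control`; the chi-square clamp at
|ad−bc| ≤ N/2 sets the corrected statistic to exactly 0 rather than a
negative value. Ties in profile argmax resolve to the lowest bin index
(`numpy.argmax` convention). Degenerate inputs raise informative errors
rather than returning sentinel values: empty window groups, zero-coverage
averaging sets, zero contingency marginals, undefined PSI.

## Known limitations

- The classifier consumes the upstream tool's FDR; it cannot rescore
  events from raw counts.
- Motif discovery is out of scope: the consensus patterns are inputs, and
  arbitrary patterns are accepted in bracket syntax.
- Alignment and peak calling are consumed as BED; the package does not map
  reads.
- Only skipped-exon events receive motif/eCLIP analysis; other event types
  (MXE, A5SS, A3SS, RI) are summarized by count only.
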
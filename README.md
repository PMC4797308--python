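# crichsplice

Cassette-exon splicing regulation by C-rich polypyrimidine tracts: a tested,
reusable analysis pipeline.

Most splice acceptor sites are preceded by a U-rich polypyrimidine tract
(PPT) recognized by U2AF65. A subset of cassette exons instead carries a
**C-rich** PPT bound by αCP proteins (also called PCBPs / hnRNPEs), and their
inclusion depends on that interaction. `crichsplice` implements the
computational side of characterizing such a regulatory program from standard
inputs — differential-splicing tables, a genome with annotation, and
eCLIP-style binding data — for RNA biologists and bioinformaticians studying
splice-site regulation:

1. **Event classification** — skipped-exon (SE) events from an rMATS-style
   table are assigned to *enhanced* / *repressed* / *background* / *excluded*
   sets from their inclusion levels. PSI (percent spliced in, ψ) per replicate
   is the length-normalized inclusion fraction

   ψ = (I/lI) / (I/lI + S/lS)

   for inclusion/skipping junction counts I, S and effective form lengths
   lI > lS. With ΔPSI = mean ψ(knockdown) − mean ψ(control), an exon is
   *enhanced* by the regulator when FDR < 5% and ΔPSI ≤ −5% (inclusion drops
   when the regulator is depleted), *repressed* when FDR < 5% and
   ΔPSI ≥ +5%, and *background* when FDR > 50% in a highly expressed gene
   (FPKM > 5.0) with inclusion neither near-always-skipped nor
   near-always-included (max condition ψ > 15%, min condition ψ < 85%).
2. **Splice-site-anchored motif profiling** — degenerate motifs (e.g. the
   C-rich consensus `[C/U][C/U][C/U][C/U]C[U/A][C/G]CC[C/U]`, or the U2AF65
   consensus `UUUUU[C/U]U`) are scanned over 500-bp windows centered on each
   cassette exon's splice acceptor and donor, and hit occurrences are binned
   in 50-bp bins advanced 1 bp at a time. Per-bin enrichment of a regulated
   group against the background set uses Fisher's exact test with
   Benjamini–Hochberg correction across bins.
3. **Motif score track** — within a sliding window (25 nt over 100-nt flank
   regions), score = (# unique nucleotides covered by motif instances) /
   (# nucleotides in the window), in [0, 1].
4. **eCLIP profiles** — FASTQ quality filtering (≥50% of bases over Q30),
   exact-sequence PCR-duplicate collapsing with barcode removal,
   single-nucleotide crosslink coverage over 100-nt exon flanks,
   per-region max normalization, and group-averaged density curves, plus
   peak–flank interval intersection.
5. **Co-occurrence statistics** — each enhanced exon is classified by
   intronic motif presence 5′ and 3′ of the exon into a 2×2 table; the
   association is tested with the continuity-corrected (Yates) chi-square,
   χ² = N(|ad − bc| − N/2)² / (r₁r₂c₁c₂), 1 d.f.
6. **Synthetic data** — a generator plants all of the above structure (motifs,
   ΔPSI shifts, FDR strata, crosslink enrichment) in a toy genome with known
   truth, so the whole pipeline is testable without external data.

## Worked example

The published co-occurrence table for a set of 749 regulator-enhanced
cassette exons counts C-rich intronic motifs 5′ and 3′ of each exon:
311 exons have the motif on both sides, 333 only 5′, 42 only 3′ and 63 on
neither side.

```python
>>> from crichsplice import ContingencyTable2x2, chi_square_2x2, derived_motif_fractions
>>> t = ContingencyTable2x2(311, 333, 42, 63)
>>> chi_square_2x2(t, continuity_correction=True)
(2.169477917751643, 0.1407740190843023)
>>> fr = derived_motif_fractions(t)
>>> fr["either_side"], fr["upstream"], fr["upstream_only"]
({'count': 686, 'percent': 92}, {'count': 644, 'percent': 94}, {'count': 333, 'percent': 44})
```

So 92% of the exons carry the motif on at least one side, 94% of those carry
it upstream of the acceptor, and in 333 the motif is restricted to the
upstream side; the 5′/3′ co-occurrence itself does not reach significance
(χ² = 2.17, p = 0.141).

The whole pipeline runs from one command on synthetic data:

```sh
crichsplice all --out-dir run --seed 1
```

which simulates a 200-gene study and leaves, under `run/`, the event
assignments, positional profiles, enrichment and contingency tables, eCLIP
density curves and a text report. With the default configuration the report
ends with

```
event classification:
  enhanced: 30
  repressed: 10
  background: 160
  excluded: 0
...
most enriched bin: group=enhanced anchor=acceptor bin_start=172 (offset -78) q=1.19e-34
```

i.e. the classifier recovers the planted 30/10/160 partition and the C-rich
motif is most enriched in the acceptor-window bin covering the planted
upstream interval (the 50-bp bin starting at offset −78 spans offsets
−78…−29, overlapping the motif planted at −30…−21).

Each stage is also available as its own subcommand (`simulate`, `classify`,
`windows`, `scan`, `profile`, `score`, `cooccur`, `eclip`, `report`); a YAML
config file can replace the flags (`crichsplice all --config run.yaml`).
See `docs/methods.md` for the underlying models and parameter choices.

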
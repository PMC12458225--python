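# pairdimer

Composite-motif analysis for transcription factors that read DNA two ways:
as **head-to-head (H-H) dimers** on inverted-repeat motif pairs, and as
**multimers** on TnG-repeat microsatellites. The motivating case is FoxP3,
the Treg master regulator, which binds inverted repeats of forkhead-like
motifs (IR-FKHM and relaxed variants) with a preferred 4-nt gap and
multimerises on TnG repeats (n = 2–5), with H-H sites often abutting short
repeats and seeding multimerisation. `pairdimer` is for computational
biologists who want to run — or stress-test on fully synthetic data — the
bespoke analyses this kind of study needs:

- **Oligo pull-down-seq enrichment** (`oligo_enrichment`): extract the
  variable site from structured reads (`NBS1–N7–TCGA–GTAAACA–NBS2`),
  tabulate all 4^7 = 16,384 site-1 sequences, compute pull-down/input
  enrichment of RPM-normalised counts, and discover "2N motifs" — 7-mers
  with two positions degenerate, each aggregating its 16 concrete
  instantiations (21 patterns per sequence).
- **Paired-motif orientation scanning** (`pair_orientation`): a 10×10×4 =
  400-pattern dictionary of 18-nt motif pairs (H-H, H-T, T-H, T-T around a
  fixed TCGA spacer), five positional shifts (0, ±1, ±2), once-per-read
  counting, and normalisation by the analytic baseline probability that a
  random variable region matches a pair at any shift given the fixed flanks.
- **Genomic pair enrichment** (`genomic_pairs`): positive-strand,
  non-overlapping scans of peak sequences with unconstrained N^g spacers,
  per-Mb frequencies, one-sided exact binomial tests against a background
  peak set, gap-size profiles (1–10 nt), blacklist subtraction.
- **TnG-repeat adjacency** (`repeats_adjacency`): a PWM scanner with exact
  p-values (discretised log-odds scores; the null distribution by positional
  dynamic programming), degenerate-run filters (6×TG … 12×T), region
  merging, signed border-to-border H-H/repeat distances with an
  aligned/divergent orientation call, signal-free background definition, and
  200-bp signal AUC comparisons stratified by repeat length.
- **Gene proximity** (`gene_proximity`): feature density (bp/Mb) in windows
  expanding 1 kb–1 Mb from gene bodies, stratified by differential-expression
  significance, and the fraction of genes with a feature within 2 kb, binned
  by adjusted p-value and effect direction.
- **Synthetic data** (`synthetic_data`): generators for both the oligo
  libraries (planted multiplicative binding models, finite candidate pools)
  and a genome bundle (FASTA, peak BEDs, blacklist, bedGraph, genes, DE
  table) with planted motif pairs, repeat tracts, aligned H-H neighbours and
  occupancy boosts — every element recorded in a truth manifest.

## Worked example

Simulate the default genome bundle (600 foreground peaks planting the
IR-FKHM pair `TGTTTAC/TGTTTAC` head-to-head at a 4-nt gap; 2,400 background
peaks planting the same pair with gaps uniform over 1–10 nt) and recover the
gap preference:

```python
from pairdimer import (GenomeConfig, simulate_genome, MotifPair,
                       gap_profile, scan_peakset, pair_enrichment)

config = GenomeConfig(seed=7)
bundle = simulate_genome(config)
pair = MotifPair(*config.pair)

profile = gap_profile(bundle.fg_peaks, bundle.bg_peaks, bundle.genome,
                      [pair], range(1, 11))
print(profile[["gap", "count_fg", "count_bg", "ratio"]].to_string(index=False))
print("preferred gap:", int(profile["argmax_gap"].iloc[0]), "nt")
```

```
 gap  count_fg  count_bg     ratio
   1         0       203  0.000000
   2         0       220  0.000000
   3         0       208  0.000000
   4       538       205 10.497561
   5         0       236  0.000000
   ...
preferred gap: 4 nt
```

The 538 foreground occurrences are exactly the planted insertions (the
truth manifest lists each one); background counts are flat across gaps, so
the foreground/background frequency ratio peaks at the planted 4-nt
spacing. The same scan feeds the exact binomial enrichment test:

```python
fg = scan_peakset(bundle.fg_peaks, bundle.genome, [pair], [4])
bg = scan_peakset(bundle.bg_peaks, bundle.genome, [pair], [4])
rec = pair_enrichment(fg, bundle.fg_peaks.total_length_bp,
                      bg, bundle.bg_peaks.total_length_bp)
```

which reports a fold change of 10.5 with p ≈ 0 (one-sided exact binomial,
trials = foreground bp) for the planted pair.

A command-line interface mirrors the library
(`pairdimer simulate genome`, `pairdimer genome-pairs`,
`pairdimer gap-profile`, `pairdimer tng-scan`, `pairdimer adjacency`,
`pairdimer pdseq-enrich`, `pairdimer pair-scan`, `pairdimer gene-prox`);
see `pairdimer --help`.

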
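# Methods

This note documents the models, statistics and numerical choices behind
`pairdimer`, what the synthetic-data generators do and do not emulate, and
the problem sizes at which the test suite exercises each claim.

## Coordinates and alphabets

All genomic coordinates are 0-based half-open (BED convention), everywhere.
Sequences use the 15-letter IUPAC DNA alphabet; degenerate matching is
set-containment per position, with `N` matching any character and every
other code failing on a non-ACGT base (soft-masked bases are uppercased on
load). Reverse complement is defined on the full IUPAC alphabet
(K↔M, R↔Y, B↔V, D↔H; S, W, N self-complementary) and is an involution,
which the suite checks as a property test.

## Oligo pull-down-seq enrichment

Reads are anchored by an exact match of the upstream flank (NBS1); the gap,
fixed site 2 (when the design has one) and downstream flank must then match
exactly. Rejections are returned as counted codes (structure mismatch,
ambiguous base, low quality), never exceptions; the Phred filter
(default ≥20) applies to variable-region positions only. The flank
sequences themselves are configurable fields of `LibraryDesign` — only
their lengths (27 and 35 nt) and the TCGA spacer are structural; the
shipped flanks are arbitrary GC-balanced placeholders, which is sufficient
because flank identity enters the analysis only through structure anchoring
and baseline probabilities, both parameterised by the design.

Count tables are dense over all 4^7 site-1 sequences (sparse for the
two-variable-site design). RPM is count / accepted reads × 1e6. Per-sequence
enrichment is `(rpm_pd + ε)/(rpm_input + ε)` with ε = 0.5 RPM by default —
additive smoothing for zero counts; the ratio is otherwise unregularised.

2N-motif discovery replaces every pair of positions of a 7-mer with `N`
(C(7,2) = 21 patterns per sequence, 21×4^5 = 21,504 distinct patterns in
total), sums counts over each pattern's 16 instantiations, and ranks
patterns by aggregated enrichment. Aggregation requires dense tables;
sparse aggregation would silently bias sums toward observed sequences. The
"coverage rank" statistic takes motifs in descending enrichment order until
every sequence in the top-q fraction (by per-sequence enrichment, q a count
quantile) is an instantiation of a selected motif, and reports how many
motifs that took.

## Paired-motif orientation analysis

An ordered pair (a, b) with spacer g is realised as:

    H-H: a + g + rc(b)      H-T: a + g + b
    T-H: rc(a) + g + rc(b)  T-T: rc(a) + g + b

so `rc(HT(a,b)) = TH(b,a)` and H-H/T-T are transpose-symmetric under strand
flip — identities the suite asserts over the full 400-pattern dictionary.
Reads are scanned with windows at shifts {−2…+2} around the variable core;
windows reaching into flanks contain the known fixed bases. A read counts
at most once per pair regardless of how many shifts match (it may support
several distinct pairs). Matching is bit-parallel: bases map to 4-bit
one-hot codes packed into two 64-bit words per 18-mer, patterns to allowed-
set masks, and a window matches iff `window & ~pattern == 0`.

The baseline probability of a pair is, per shift, the product over pattern
positions of 1 or 0 (fixed design base allowed / not allowed) or
|allowed|/4 (variable position); shifts combine by the independence
approximation `1 − Π(1 − p_s)`. The exact union over 4^14 variable states is
not computed; the approximation errs only through molecules matching at
multiple shifts and is validated against Monte-Carlo estimates (10^6
molecules, agreement within 3 standard errors) for pairs spanning three
orders of magnitude of baseline. Zero-baseline pairs are flagged and their
normalised value set to 0. Display scaling divides one or two matrices by
their (common) maximum ×100.

The default 10-motif seed set (five forkhead-like "group 1" patterns
containing TGTTT/TGTTG cores, five GCAT-core "group 2" patterns) is a
configurable input; users holding an authoritative motif table should
substitute it via the motif-file option.

## Genomic pair enrichment

Peak sequences are scanned on the positive strand only; negating the strand
would only permute the orientation matrices (checked as a property).
Per-pattern scans are greedy and non-overlapping — after a match the scan
resumes past it — while different patterns may overlap. Genomic spacers are
matched as N^g: the TCGA spacer is an artifact of oligo construction, not a
binding requirement.

Counts are normalised per Mb of total (unmerged) peak length. Enrichment of
foreground over background uses a one-sided exact binomial test with
trials = foreground bp and success probability the background per-bp rate,
floored at one count per background bp when the background count is zero; fold changes take
a 0.5-count continuity correction in that case. Significance is raw
p < 0.05 (a Benjamini–Hochberg option exists but is off by default, matching
the headline analysis style). The binomial parameterisation (trials = bp
rather than possible match positions) is isolated in one function and
verified against direct pmf summation.

Gap profiles rebuild each pair at spacers 1–10 nt and report per-Mb
frequencies in both peak sets plus the argmax gap of the
foreground/background ratio.

## TnG-repeat scanning and adjacency

The PWM scanner reimplements a FIMO-style exact-p-value scan: log-odds
scores (base 2, probabilities regularised by pseudocount
`(p + pc)/(1 + 4pc)`, default pc = 0.01) are discretised per position to an
integer grid (default 1,000 bins per position); the exact distribution of
the discretised total under the background model is obtained by positional
convolution, giving tail probabilities P[T ≥ t]. Matches are windows with
p < threshold (default 8e-5), scored on both strands; minus-strand matches
are reported in plus coordinates with strand "−". The DP is verified
exactly (to 1e-12) against brute-force enumeration for widths ≤ 6, and
p-values are monotone non-increasing in score across the whole table.

The default TnG matrix is built in-package by equal-weight tiling of
TTG/TTTG/TTTTG registers over 12 positions with a uniform background. Any
period-mixture repeat matrix of this kind scores poly-T (and hence poly-A on
the opposite strand) highly — which is exactly why the degenerate-run
filters exist: matches containing any 12-nt dinucleotide run
((TG)₆, (AC)₆, (TA)₆, (TC)₆, (AG)₆, (CG)₆) or 12-nt homopolymer are removed.
The filter is idempotent. An externally calibrated matrix can be supplied as
a TSV (rows = positions, columns A C G T); all scanner correctness tests use
small synthetic PWMs with exhaustive oracles, so nothing depends on the
default matrix.

Overlapping (≥1 bp) matches merge transitively into repeat regions
(abutting matches stay separate); region strand is that of the best-scoring
constituent, ties to "+". Overlapping H-H occurrences merge into unique
sites. For each H-H site the nearest repeat by |border-to-border distance|
is reported with a signed distance: positive when the repeat is downstream,
negative upstream, 0 on overlap **or exact abutment** (the 0-gap adjacency
class). Orientation is "aligned" when a plus-strand (TnG-face) repeat lies
upstream or a minus-strand (CAn-face) repeat lies downstream — i.e. the
repeat reads away from the site so the proximal half-site extends into it.
Distance-0 cases are sided by the repeat midpoint relative to the site
midpoint; equidistant ties go downstream. Reflecting the chromosome flips
distance signs and swaps the two aligned clauses (property-tested).

Signal AUC is the base-resolution sum of a piecewise-constant coverage
track over a ±100 bp window (no interpolation; windows truncate at
coordinate 0 with a warning). Foreground-free background regions are open
chromatin ≥10 kb from every foreground peak (regions on chromosomes without
foreground peaks qualify) with center-window AUC below the minimum over
foreground peaks. The length/adjacency stratification compares log2(AUC+1)
medians across {short ≤20 bp, long ≥40 bp} × {adjacent: distance 0 and
aligned; far: ≥1 kb from every H-H site}; intermediate lengths and
distances are excluded, and empty groups are flagged rather than fatal.

## Gene proximity

Feature density is feature **base pairs** per Mb (the merged feature
footprint clipped to the window — overlapping features are not double-
counted), computed in windows expanding the gene *body* by 1 kb–1 Mb on both
sides and averaged within DE groups (significant: adjusted p < 0.05;
missing p treated as 1). The 2-kb analysis reports, per adjusted-p bin
(default edges 0, 1e-5, 1e-3, 0.05, 0.5, 1) and optionally per effect
direction, the fraction of genes whose 2-kb-expanded body overlaps ≥1
feature; empty bins are NaN, not 0. Enlarging the expansion can only turn
misses into hits (monotonicity is property-tested).

## Synthetic data: what it emulates, and what it does not

**Oligo libraries.** Input reads draw variable regions uniformly; pull-down
reads are drawn with replacement from a finite pool (default 10× the read
count) with probability proportional to a multiplicative weight: base 1.0
times a bonus per satisfied condition. Three condition types cover the
study contrasts: *pair bonuses* (the molecule matches an orientation-
resolved pair pattern at a tolerated shift — the head-to-head binder),
a *site-2-only bonus* (meaningful for the fixed-site-2 design, where it
makes enrichment independent of site 1), and a *monomer bonus* (a single
in-register half-site, either site, either face — the orientation-symmetric
single-FKHM binder used for the non-dimerising control in the two-variable-
site design, where a site-2-only rule would itself complete H-H patterns
and spuriously bias HH). The default planted pair is the degenerate
TGTTTNN/TGTTTNN head-to-head (bonus 300): a fully concrete 14-mer pair
occurs at 4^-14 and would be absent from any desk-scale pool. The finite
pool mimics library bottlenecking (realistic duplicate statistics) at the
cost of extra count variance. Qualities are uniform Phred 30; no sequencing
error model — quality filtering is exercised by construction, not
emulation.

**Genome bundle.** Chromosomes are built left-to-right from iid background
(GC 0.42) with 0.6–2 kb spacers between planted elements: foreground peaks
(default 600 × 300 bp, 90% planting the pair at a 4-nt gap), background
peaks (2,400 × 300 bp, 90% planting it with gaps uniform on 1–10), and
repeat tracts (TTG/TTTG/TTTTG periods; short 12–20 bp, long 40–60 bp, half
of each given an abutting, aligned IR-FKHM site). The last chromosome
carries only background peaks and far-placed genes, so foreground-free open
chromatin exists unambiguously. Coverage is baseline 1.0 plus noisy boosts:
bound peaks +5, long repeats +8, short repeats with an adjacent H-H +8,
short repeats alone +2 (sd 0.5) — encoding the study condition that
adjacency rescues short repeats specifically. DE-significant genes
(padj log-uniform 1e-8–0.049, log2FC positive in 80% — up on factor loss)
are placed 0.1–0.9 kb downstream of planted elements; non-significant genes
live on the feature-free chromosome. truth.json records every planted
element, OCR bound/free labels, and blacklist targets. All randomness flows
from one master seed via named substreams; identical seeds give
byte-identical bundles.

Passing tests on these bundles therefore demonstrates correct recovery of
*planted* structure under iid background — they say nothing about chromatin
realism, repeat families other than TnG, overlapping regulatory elements,
or mapping artifacts, which real peak sets contain.

## Problem sizes and statistical design of the tests

Enrichment-flatness checks (null model; site-2-only flatness) run at
4×10^5 reads per sample: with ~21,500 aggregated patterns, extreme-value
noise alone reaches ≈1.25 at this depth, leaving clear margin under the
1.5 / 2.0 bounds asserted. Orientation recovery runs at 2×10^5 pull-down
reads (head-to-head totals ~6× the runner-up under the planted model);
the no-preference control is asserted as a chi-square uniformity test
(p > 0.01) because orientation totals there are chance-level counts, for
which a fixed percentage band would be noise. Monte-Carlo baseline checks
use 10^6 molecules. Genome-scale recoveries use the default bundle
(600/2,400 peaks, ~5 Mb total); exact planted-vs-recovered identities hold
because an 18-nt pattern with 14 specified positions has a ~4^-14 per-bp
chance rate. Exact-k repeat-region recovery scans planted-tract
neighbourhoods, mirroring peak-restricted scans: at p < 8e-5 a genome-wide
scan necessarily contains ~5×10^-5/bp chance windows, which is a property
of the threshold, not a defect of the scanner. The full suite runs in
about a minute on one CPU.

## Known limitations

- The shift-combined baseline is an independence approximation (validated
  within Monte-Carlo error at desk scale, but not exact).
- The exact-binomial trials are foreground base pairs, not match positions;
  for patterns comparable in length to peaks this overstates trials
  slightly (choice isolated in one function).
- The default TnG PWM is a constructed stand-in; analyses of real data
  should substitute the calibrated matrix.
- Density is bp-based; studies counting feature *occurrences* per Mb will
  differ by the mean feature length.
- The generators plant one pair per peak at most and do not model peak
  width variation, GC heterogeneity, or inter-element correlation beyond
  the explicit H-H/repeat adjacency.
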
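# Methods

This note documents the statistical model behind `methocc`: what each
estimator computes, the generative model the test suite runs against, the
numerical conventions, and the design choices that were genuinely open.

## Coordinates and formats

All internal coordinates are 0-based, half-open. BED and bedGraph are
native to that convention; cytosine reports are 1-based on disk and
shifted by exactly one when calls are joined onto a genome
(`attach_calls`). Strand `.` is allowed on intervals, never on cytosine
records. bedGraph values are rendered with six significant digits, so a
write/read round trip preserves values to 1e-5 relative — bedGraph is the
canonical signal format; bigWig is not required.

## Methylation statistics

A cytosine site lives on one strand; its di-/tri-nucleotide context is
read 5'→3' on that strand (for a minus-strand site this means leftward
along plus coordinates, complemented). Contexts truncated by the
chromosome end or containing an N are `NA` at the affected rank and are
excluded from that rank's statistics.

* site level: `m_i = count_modified / count_total`; sites with zero
  coverage are retained but flagged and excluded from means. The minimum
  coverage for inclusion in means defaults to 1 read and is exposed.
* region mean: `m'_CX`, the unweighted mean level over covered sites of
  context CX in the region.
* density: `N_CX · m'_CX / L` — equivalently the sum of covered-site
  levels over the region length. Stored per bp, reported per kb. The
  density is bounded by `N_CX / L`, with equality only when every site is
  fully methylated.
* genome-wide tables: di-context composition, the modified-cytosine
  composition, and mean level per trinucleotide. The modified-composition
  table defaults to expected-count weighting (each covered site
  contributes its level); a binary mode (level ≥ 0.5) is provided because
  the weighting behind published pie-chart summaries of this kind is
  typically unstated.
* BS−TAB resolution: BS-seq reads mC+hmC and TAB-seq reads hmC alone, so
  `hmC = m_TAB` and `mC = max(0, m_BS − m_TAB)`; negative differences are
  sampling noise, clamped to zero and counted.
* conversion rate: pooled modified/total basecalls over the unmethylated
  λ spike-in, with an exact (Clopper–Pearson) 95% CI. For 0 modified calls
  out of n the upper bound is ≈ 3.7/n, the familiar rule-of-three
  magnitude.

## Occupancy and the Input model

Fragments are reduced to one position — start+shift on the plus strand,
end−1−shift on the minus strand — and counted in fixed windows; the
trailing partial window is dropped and off-partition fragments are
tallied, so window counts plus losses always equal the library size.
RPKM = counts / (library/10⁶) / (width/10³). The occupancy track is
`log2((chip_rpkm + ψ)/(input_rpkm + ψ))` with ψ = 0.5 RPKM by default
(the pseudocount is a package choice; nothing in the underlying method
fixes it). The shift defaults to half the fragment length (67 bp for
134 bp fragments); a literal full-fragment-length mode is available
because published descriptions of the shift are ambiguous between the
two conventions.

The Input model is ordinary least squares of ChIP on Input window counts;
R² = 1 − SS_res/SS_tot. Residual outliers are labelled two ways:

* `quantile` — the lowest q_low fraction of residuals is depleted and the
  highest q_high enriched; defaults 4.1% / 1.7% reproduce a published
  window partition whose construction was not otherwise specified.
* `zscore` — standardised residuals beyond ±2; this is the statistically
  motivated mode and the one used for synthetic recovery, since the
  quantile mode labels a fixed fraction regardless of signal.

`neutral_r_squared` is a fresh fit restricted to neutral windows. Windows
with more than 50% N bases are excluded from fits. The AT-flank
comparison flags an isolated methylated site (no neighbour within ±50 bp,
configurable) when a maximal run of ≥4 consecutive A/T bases *starts*
within ±13 bp of it, and reports group means with a bootstrap 95% CI of
the difference.

## Summits and profiles

The summit caller is an explicitly simplified stand-in for a full peak
caller. Enrichment `e = log2((chip + ψ)/(input·r + ψ))` (r = library-size
ratio) on fine windows (≤50 bp) is smoothed by a running mean; candidate
peaks are maximal runs with `e` above a threshold; each run is kept if its
summed ChIP count clears a Poisson upper tail (p < 1e-5) against
`r × λ_local × run length`, where λ_local is the largest of the run-scale,
5 kb-local and genome-wide Input means. Taking the maximum stabilises the
background exactly where raw in-run Input fluctuates low, which is
otherwise the dominant source of false summits. The summit is the argmax
of smoothed enrichment within the run, leftmost on ties. The caller's
contract is summit position, not score.

Profiles average a signal in fixed bins around anchors. With an even bin
count the anchor sits on the boundary between the two central bins, so
"central peak" means the maximum falls in either. Minus-strand anchors are
column-reversed. Anchors whose flank leaves the chromosome are dropped and
tallied. Methylation-density profiles reuse the region density statistic
per bin; occupancy profiles length-weight the overlapping track windows.
Random-region controls draw uniformly from non-N, non-excluded positions.

## Multiscale domains

The segmentation runs a geometric smoothing ladder: at scale s both count
tracks are mean-smoothed over `w0·2^s` bp (defaults w0 = 100 bp,
13 scales, 100 bp → ~400 kb — covering sub-kb CGI-scale depletions
through the longest domains a 5 Mb chromosome can hold). The enrichment
score is the smoothed log2 ratio; candidate segments are maximal
same-sign runs with |score| ≥ threshold; each is kept if a two-sided
binomial test of its raw ChIP count against expectation r·Input
(p_chip = r/(1+r)) gives p < 1e-6. Segments carry the scale index, the
segment-mean signed score, and annotations (mCG, mCAC and combined
density per kb, GC fraction). Mappability is assumed uniform. Nested
segments across scales are all reported by default; an optional pruning
pass keeps the most significant segment per overlapping same-sign locus.
Scale indices here are internal to this ladder and are not comparable to
scale numbers of any external multiscale tool.

Domain-recovery tests plant constant-fold domains over flat Input and
segment at the scale nearest the planted length with the threshold at the
detection midpoint `log2(fold)/2 − log2(r)`; the `−log2(r)` term matters
because planting enrichment itself inflates the ChIP library total, and
omitting it systematically narrows recovered segments.

CGI overlap of short depleted segments is scored against an empirical
null of position-shuffled segments (lengths and chromosomes preserved),
`p = (1 + #{null ≥ observed}) / (N + 1)`.

## Expression and the global scale

Size factors are median-of-ratios: per-gene geometric means across
samples form a pseudo-reference and each sample's factor is the median
count/reference ratio over genes positive in every sample; normalised
counts are count/factor. A global-scale correction multiplies one
condition's factors by a constant. This is the device that encodes a
measured change of RNA *per cell* — invisible to any per-library
normalisation. Two directions arise in practice: with real depth-
normalised libraries the knockout's 15% reduction is encoded by
multiplying KO factors by 1.15 (shrinking its normalised counts toward
the per-cell truth); with the synthetic design below, where sequencing
depth is proportional to cellular RNA and the 0.85 sits in the counts,
the same operation with the reciprocal rate (×1/1.15 ≈ 0.87) removes it.
The residual |log2(0.85 × 1.15)| ≈ 0.033 measures how close the ×1.15
rate is to exactly cancelling a true 0.85 scale.

The differential test is a self-contained moderated NB Wald test, not a
wrapper around any DE package: per-gene moment dispersions (pooled
within-group variances of normalised counts) are clipped to
[1e-8, 10], a trend `a + b/mean` is fitted by least squares, and the
working dispersion is 0.3·gene + 0.7·trend. The relatively strong
shrinkage reflects how noisy a 3v3 moment estimate is; the weight is
exposed (`DEOptions.shrinkage_weight`). The Wald statistic
`log2FC / SE(log2FC)` (delta-method SE with size-factor-aware variance)
is referred to the standard normal, the convention for NB Wald tests; a
t reference with the residual 4 df is far too heavy-tailed at this
design size (type I ~0.01, power near zero). BH adjustment runs over
genes with positive normalised counts (and in the full pipeline, over
genes passing the TPM filter).

Gene classes: `filtered` if TPM < 5 in all samples; `up`/`down` if
padj < 0.05 with the matching sign; `unchanged` if padj > 0.5 and
|log2FC| < 0.01; `other` otherwise. Every gene gets exactly one class.
Gene occupancy is the window-overlap-weighted mean of the log2 track over
the gene body and over body ± 100 kb (the flanked mode is the default
because domain-scale binding extends well beyond gene bodies; body-only
is available). Rolling curves use 400-gene windows at step 80 over genes
ranked by occupancy, ties kept in original order; window curves use
consecutive groups of 1000 ranked windows with the remainder dropped.

## The generative model

Everything above is tested against `synthetic_data`, which emulates the
statistical structure of a neuronal methylome/occupancy/expression study
at desk scale (defaults: 2 chromosomes × 5 Mb, ≤5000 genes; every
acceptance run fits this).

* **Genome** — i.i.d. bases on an isochore-like GC landscape (mean 0.42,
  sd 0.04, ~100 kb correlation scale), CG dinucleotides outside CGIs
  broken with probability 0.75, and 40 planted 2 kb CGIs drawn GC-rich
  (p_C = p_G = 0.35). The landscape is what makes Input coverage
  realistically predictable from composition; with i.i.d. bases alone,
  window GC is essentially constant and the Input model has nothing to
  explain.
* **Methylome** — per-site binomial calls at Poisson(30) depth: mCG 0.8
  outside CGIs and 0.05 inside; mCAC 0.12 inside "high" domains and 0.02
  elsewhere (domains tile each chromosome, lengths uniform in
  50–400 kb); all other CpH contexts at 0.01; a global 0.5% non-conversion
  rate; an optional TAB channel with 3% hmCG. Optional mCAC clusters for
  summit emulation are triangular tapers (peak 0.9, halfwidth 100 bp)
  because flat-topped clusters make the aggregate profile's argmax
  wander over a plateau, unlike the sharply peaked profiles the cluster
  is meant to emulate.
* **ChIP/Input** — per 1 kb window, Input intensity = 50 fragments ×
  2·expit(15·(GC − mean)); ChIP multiplies it by
  `exp(0.03 · (combined mCG+mCAC density/kb − mean))`; counts are
  Poisson; fragments are fixed-length 134 bp intervals with uniform
  starts (the analysis only consumes shifted positions). β = 0.03 per
  site/kb puts occupancy spans at ~±0.3 log2 units, the magnitude real
  MeCP2 tracks show; the coupling uses the *combined* density, with the
  contributions controlled jointly, since the data the model emulates do
  not separate the mCG and mCAC dose–response curves.
* **Expression** — log-normal baselines (median ≈ 100 counts), NB
  dispersion 0.02 (CV ≈ 14%, typical of isogenic-mouse bulk RNA-seq; at
  CV ≳ 20% a 3v3 design cannot deliver 80% power on |log2FC| = 1 even
  with oracle dispersions, so larger values change what any test can
  show); 30% of genes couple their KO log2FC as 3 × gene occupancy and
  their OE log2FC with the opposite sign; all KO expectations are then
  multiplied by 0.85. Truth records pre-scaling fold-changes. Depth is
  proportional to cellular RNA (a spike-normalised design), which is why
  unit size factors are the honest "uncorrected" normalisation and both
  median-of-ratios and library-size factors silently absorb the global
  scale — the phenomenon the correction exists to undo.

Each stage draws from `default_rng(seed + stage_offset)` so changing one
stage's parameters never perturbs another stage's draws, and all outputs
are pure functions of the configuration.

## What the synthetic studies do and do not show

Passing recovery tests demonstrates that the estimators are correctly
implemented, calibrated under their own model, and powered against the
planted effect sizes. They do not demonstrate robustness to what the
generator omits: mappability and blacklist structure, fragment-length
variation and library chemistry, bisulfite conversion failure beyond one
global rate, realistic read sequences or sequencing error, diploidy,
isoform structure, or dispersion outliers in expression. Quantities such
as the Input-model R² (~0.57 at default depth) are properties of this
generator's composition bias, not estimates of any published value.

A statistical caution that applies to real data too: windows within a
domain share the GC landscape, so window-level two-sample tests between
domain classes are anticonservative; the tests here use whole domains as
sampling units.

## Numerical conventions and degenerate inputs

* Running means are centred with window clipping at the edges.
* Summit ties: leftmost argmax. Segment scores: segment-mean of the
  smoothed log2 ratio, sign-checked against the run's sign.
* `fit_input_model` requires ≥3 windows and positive Input variance;
  zero-coverage regions yield density 0 with an undefined (NaN) mean;
  empty intervals are unrepresentable (`0 ≤ start < end` is enforced at
  construction).
* The binomial segment test uses the doubled-smaller-tail convention,
  capped at 1; expectations below machine floor are clamped.
* BH adjustment excludes untestable genes (no counts in either group);
  identical groups get log2FC exactly 0 and p exactly 1.
* All pseudo-random draws, including bootstraps and shuffles, take
  explicit seeds.
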
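# Methods

This note documents the models, defaults and numerical choices behind
`modscore`, and what the synthetic-data-based tests do and do not establish
about real data.

## Bulk differential expression

**Model.** Counts for gene *g* in sample *j* are treated as negative
binomial with mean `s_j · μ_g(condition)` and variance `μ + α μ²`
(gamma–Poisson convention; `α` is the dispersion). Size factors `s_j` are
median-of-ratios: the median over genes (restricted to genes expressed in
every sample) of the ratio of a sample's count to the gene's geometric
mean, rescaled to geometric mean 1. When no gene is expressed everywhere,
total-count scaling is the fallback.

**Dispersion.** Each gene yields a method-of-moments estimate
`α̂_g = (s²_g − μ̄_g)/μ̄²_g` from the within-group variance pooled over the
two conditions. The default (`dispersion="pooled"`) averages **all finite
per-gene estimates, negatives included**, into a single α shared by all
genes, floored at 1e-8. Two points matter here:

* With 4 replicates per group, per-gene variance estimates carry ~6
  degrees of freedom; plugging them into a Wald statistic gives heavy
  tails and an inflated false-positive rate. Pooling across genes borrows
  strength the way shrinkage estimators in the established DE packages do,
  and is appropriate for the constant-dispersion data this package's
  generator produces. A `dispersion="per-gene"` mode exists for data where
  dispersion genuinely varies, with the caveat that it is anticonservative
  at small n (empirically ~0.10 at nominal 0.05 on 4+4 null simulations).
* The per-gene moment estimate is right-skewed, so its median is biased
  low (≈ 0.043 for a true α of 0.05 in simulation), which propagates into
  ~0.065 empirical type-I error at nominal 0.05. The mean over all finite
  estimates is unbiased (each per-gene estimate is unbiased; skewness does
  not affect the mean), and restores calibration (≈ 0.050 across seeds).

**Test statistic.** `log2FC = log2((μ̂_T + 0.5)/(μ̂_C + 0.5))` on normalized
group means. The 0.5 pseudocount keeps extreme genes finite (relevant for
dominant-negative-style contrasts where many genes collapse to zero); its
bias at base mean ≥ 50 is below 0.01. The Wald statistic divides by a
delta-method standard error, `SE² = [v(μ̂_T)/(μ̂_T+0.5)² +
v(μ̂_C)/(μ̂_C+0.5)²]/ln²2` with `v(μ̂) = (μ̂ + αμ̂²)/n`, and is referred to a
standard normal (two-sided). BH adjustment runs over the tested
(post-filter) genes only, matching the filter-then-test order of the
pipeline.

**Rules.** The pre-filter keeps genes with ≥ `min_count` (10) counts in
≥ `min_samples` (4) samples — i.e. one full replicate group in the 4+4
design this pipeline targets. DEG calling uses strict inequalities
(`padj < cut`, `|log2FC| > cut`): a gene at exactly padj = 0.05 or
|log2FC| = 1.5 is not called. The stringent profile (padj < 1e-10, same
fold-change cut) is intended for contrasts whose DEG count under the
standard rule would be dominated by low-expression noise.

**What is deliberately not implemented:** fold-change shrinkage, outlier
(Cook's-distance-style) handling, and independent filtering. Consequently
numerical identity with any published package's output is not a goal;
correctness is established by null calibration, planted-effect recovery,
exact symmetry/invariance properties, and brute-force oracle equivalence of
the filter rules.

## Single-cell processing

**QC.** A cell is excluded if it has fewer than 500 or more than 4,000
detected features (genes with count > 0), more than 15,000 total counts, or
more than 20 % mitochondrial counts (genes flagged by the `MT-` prefix at
I/O time). All four comparisons are strict, so cells sitting exactly on a
bound are retained — this follows the exclusion rules being phrased as
"less than / more than". A zero-count cell fails the minimum-features rule.
Per-rule violation counts are reported; a cell violating several rules
counts under each.

**Normalization.** `x = ln(1 + count/total · 10⁴)` per cell, the standard
library-size log transform. Depth invariance (doubling a cell's counts
leaves its vector unchanged) holds exactly.

**Marker detection.** Cluster-vs-cluster DE uses the two-sided Wilcoxon
rank-sum test (normal approximation with tie correction) per gene on
normalized values, BH-adjusted, with
`log2FC = log2((mean expm1(x_A)+1)/(mean expm1(x_B)+1))`. No minimum-
expression or fold-change pre-gates are applied by default; the test is a
deliberate rank-based stand-in for cluster-marker functions in single-cell
toolkits, not a wrapper around one. Constant genes get p = 1.

**Per-cell modulation score.** The published figure defines the score only
as "top DE genes … used to determine a score"; the formula here is the mean
of per-gene z-scores (expression standardized across cells) over the
signature genes present, with equal weights. This choice is simple, is
invariant to genes outside the signature, and centers the score at 0 when
all signature genes are present. The default signature is the seven
CMC-vs-differentiated markers `IBSP, TMEM119, VCAM1, DCN, LUM, MXRA5,
PDPN`. A control-bin module score (Seurat/scanpy `AddModuleScore` style)
is a known alternative and is out of scope.

**Modulation reference.** `build_modulation_reference` pools the chosen
modulated clusters against the differentiated clusters, keeps genes with
padj < 0.05 (no fold-change cut — the in-vivo axis wants the full DE gene
set), and orients each gene by the sign of its log2FC. Cluster sets are
parameters, so both the all-modulated axis and the CMC-only axis variant
are expressible; genes with log2FC exactly 0 are dropped at construction.

## Composite score

Contributions are `s_g · log2FC_g^vitro` over genes present in both the
variant's DEG list and the reference; the total is their sum, unnormalized.
A size-normalized total (`total/n_intersect`) is additionally exposed as
`CompositeScore.normalized` for cross-variant comparison but is clearly a
package extension, not part of the published procedure. The quadrant
decomposition assigns each intersecting gene to one of four cells by
(in-vivo sign × in-vitro sign); the four sums partition the total exactly.
An empty intersection is a warning, not an error, and scores 0. Which DEG
rule feeds the score is the caller's choice per variant; the demo uses the
standard rule for all variants, and the stringent profile can be passed for
variants whose standard-rule DEG list would be very large.

## Image quantification

Channels are thresholded by Otsu's method (a fixed-threshold mode exists
for bit-exact regression tests); this approximates, but is not identical
to, ImageJ's "Default" auto-threshold. Colocalization is pixel-wise AND of
binary masks, and nuclei are counted as 8-connected components with a
minimum area of 20 px (no size gate is stated in the original workflow; 20
px is below half the area of the smallest plausible nucleus at the
simulated scale and is configurable). Counting colocalized nuclei as
particles of the AND mask — threshold, AND, count — is the faithful mode
and the default.

Transduction efficiency = colocalized (nuclear ∧ reporter) particles over
all nuclear particles, ×100. Transduced proliferation = triple-colocalized
(nuclear ∧ reporter ∧ EdU) particles over nuclear ∧ reporter particles.
Untransduced proliferation = (nuclear ∧ EdU ∧ ¬reporter) particles over
**all** nuclear particles — reported as a percentage of all cells. A blank
channel yields an empty mask (0 %) rather than a threshold error.

Wound closure uses cell-free areas: the wound at each timepoint is the
largest connected background component of the thresholded monolayer mask
overlapping the t0 ROI, and closure is `((A₀ − A_t)/A₀)·100`. Negative
closure (wound growth) is allowed and flagged.

## Synthetic generators

The generators define the conditions under which the pipeline is validated.

* **Bulk**: 2,000 genes × (4+4) samples by default, NB with α = 0.05 and a
  flat baseline mean of 100; planted genes change the treated mean to
  `baseline · 2^log2FC`. Gene lengths are uniform on [500, 5000] bp unless
  given. The flat baseline is a deliberate simplification: it makes
  calibration statements crisp at the cost of realism (no mean–dispersion
  trend, no expression-dependent power differences).
* **Single cell**: populations share a lognormal(0, 1) relative-expression
  profile; each population's marker genes are shifted up by 2 in log2.
  Marker baseline weights are pinned to the 95th percentile of the profile
  because the marker genes this emulates (`CNN1`, `DCN`, `IBSP`, …) are
  highly expressed in their cell types — markers landing in the
  low-expression tail would be undetectable at any realistic depth and
  would make marker-recovery checks meaningless. Depth is lognormal
  (median 3,000 counts, σ = 0.25), counts NB with α = 0.1 scaled per cell,
  and the mitochondrial fraction Beta-distributed around 5 % and spread
  over a 13-gene `MT-` block so the QC stage computes the percentage
  rather than reading it. QC outliers are planted constructively so that
  each violates exactly its designated bound (e.g. high-count cells draw
  ~20,000 counts from a restricted 3,200-gene subset so their feature
  count stays inside [500, 4000]); ordinary cells are re-drawn (seeded, up
  to 20 attempts) in the rare case a draw strays outside a bound.
* **Imaging**: nuclei are non-overlapping disks (rejection sampling with a
  10·n attempt budget; failure raises rather than overlapping), with
  reporter and EdU disks stamped for the designated subsets —
  `⌈transduced_fraction · n⌉` reporter-positive nuclei, rounded counts for
  the two proliferation fractions. Migration images are rendered as a
  confluent monolayer (uniform foreground) with a centered cell-free disk
  whose radius shrinks over timepoints; this emulates stitched
  low-magnification wound images, where the monolayer reads as continuous
  foreground, and keeps wound areas exact up to pixelization. Closure is
  simulated by shrinking the disk, not by cell motion.

**What passing tests show — and don't.** The generators have constant bulk
dispersion, no mean–variance trend, no batch effects, no doublets or
ambient RNA, no segmentation-hard imagery (touching nuclei, uneven
illumination). Passing calibration and recovery under these conditions
demonstrates the implementation is correct and internally consistent; it
does not certify performance on real data with those complications.

## Problem sizes and determinism

Default validation sizes: 2,000 bulk genes with 4 replicates per group; 300
cells per population (2,000-gene panel for the end-to-end trials, 6,000 for
QC-focused runs so the 4,000-feature bound is live); 200-nucleus fields;
100 seeded runs for direction-recovery rates; 1,000 shuffles/fixtures for
permutation and algebra checks. Every stochastic step takes an explicit
seed (`numpy.random.default_rng`); identical spec + seed reproduces output
bit-for-bit, and the demo report regenerates identically under a fixed
config.

## Known limitations

* The NB test's pooled dispersion assumes exchangeable dispersion across
  genes; strongly gene-specific dispersion calls for the per-gene mode
  plus more replicates.
* TPM-based overexpression folds are compositional: a very strong planted
  effect inflates the treated libraries' normalization denominator, so TPM
  folds land a few percent below count-scale folds (visible in the demo).
* The rank-sum marker test ignores donor/batch structure (no
  pseudobulking); cluster labels are taken as given, and clustering itself
  is out of scope.
* Otsu thresholding assumes bimodal intensity histograms; low-contrast or
  heavily vignetted fields need preprocessing that is out of scope here.
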
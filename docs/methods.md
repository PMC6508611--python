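# Methods

This note records the statistical model behind each stage of `txscore`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices a maintainer should know
about.

## Data model

An `ExpressionStudy` is a complete genes × samples matrix of log2-scale
expression values plus a design that assigns every sample to a condition
and marks exactly one condition as healthy control and one as disease
control; all others are treatment arms, optionally tagged prophylactic or
therapeutic.  Rows with any missing value are dropped at load (the
framework assumes genes measured in all samples), and all loaders are
column-order insensitive.  Functional categories come from GMT files and
are intersected with the measured gene universe at load; categories
falling below `min_category_size` (default 3) are dropped with a warning.
The universe for every enrichment is the measured gene set, not the
genome — using the genome would inflate every test.

## Differential expression

Per gene, a one-way fixed-effects layout with pooled (homoscedastic)
residual variance across all conditions; fold-changes are differences of
group means because the data are already log2.  Each non-baseline
condition is compared to the baseline with Dunnett's many-to-one
procedure.  Because the design is identical for every gene, the null
distribution of max |T_j| is computed once per contrast: conditioning on
the control-group mean and the pooled scale estimate factorises the CDF
into a product of normal-CDF differences, integrated with 48-node
Gauss-Hermite (control mean) × 48-node Gauss-Legendre (scale, in
probability space) quadrature and tabulated on a 1500-point monotone
interpolation grid.  Agreement with `scipy.stats.dunnett` (which solves
the same problem through multivariate-t integration) is ~2e-5, and with
a 10^6-draw Monte-Carlo simulation of the max-|t| null ~1e-3; the
two-condition case reduces exactly to the pooled two-sample t-test.

Choices worth knowing:

* "Adjusted p" means the Dunnett family-wise adjustment *within* a gene.
  An additional Benjamini-Hochberg pass across genes is available
  (`bh_across_genes`) but off by default; with it on, DE counts are no
  longer comparable to the per-gene-familywise convention.
* Genes with zero total variance are defined non-significant (log2FC 0,
  p = 1).  Zero residual variance with a real mean difference yields
  p = 0 rather than an error.
* DE thresholds default to |log2FC| ≥ 1 and adjusted p ≤ 0.05.

## Gene sets and trichotomy

Three nested sets summarise a study: the disease set (DE in disease vs
healthy), the extended set (DE vs healthy in disease or any arm) and the
full union (DE vs either baseline anywhere).  Per arm, restored / not
restored / altered are plain set algebra on the disease set and the arm's
DE-vs-healthy set.  "Altered" is defined against the healthy baseline by
default; an inclusive mode additionally counts genes DE only versus the
disease control, because the most inclusive union can contain such genes.
Exclusive intersections follow UpSet semantics (elements in exactly one
label combination; counts sum to the union size) and total pairwise
overlaps are reported alongside, since both flavours are informative.

## Clustering

DE genes are clustered on their log2FC-vs-healthy profiles across all
conditions with Ward's minimum-variance criterion on Euclidean distances
(Euclidean is required for Ward's variance interpretation).  The cluster
number is the argmax of mean silhouette width over k in [2, 15] by
default, ties broken toward smaller k for parsimony.  All-identical
profiles degrade to k = 1 with a warning rather than an error.  The
selected k on real data can be sensitive to the search range; the range
is therefore a configuration field, not a constant.

## Distances and efficiency scores

The profile distance is the mean absolute difference of per-gene log2FC
(a true metric); against the zero profile it is the distance from the
healthy state and serves as the treatment-efficiency proxy.  The
efficiency score of a category is the log10 ratio of the mean absolute
log2FC versus the disease control over that versus the healthy control,
evaluated over the category's DE genes.  The ratio admits two readings —
mean of absolute values versus absolute value of the mean — which
disagree whenever a category mixes signs (e.g. vs-healthy fold-changes
+1 and −1 give denominator 1 in the first reading and 0 in the second).
`mean_of_abs` is the default because it is the stable reading; the other
is exposed as `abs_of_mean`.  The denominator is guarded by
epsilon = 1e-8 and scores are capped at ±12 for reporting, so the
guarded-zero case is visible but finite.  No significance test is
attached to efficiency scores; they are descriptive.

## Random-forest classification

`rf_select` trains `n_models` forests (default 1000; 500 trees, 10
variables per split) on independent stratified 70/30 train/test splits
and keeps the model with the lowest out-of-bag error, computed on each
model's own 70% training portion — the held-out 30% stays untouched for
test accuracy and the confusion matrix.  OOB-based confusion on the
training portion is emitted as well, since both conventions are in use.
Ties in OOB error resolve to the lowest model index; `mtry` is clamped to
the feature count; everything is reproducible from one integer seed
(per-model split and forest seeds are drawn from a seeded generator).
Category-level features are the mean log2 expression of each category's
DE genes — aggregation cancels per-gene noise, which is why
category-level accuracy is expected to match or beat gene-level accuracy
when signal is block-structured.  The PCA embedding is a column-centred
SVD of the samples on a chosen feature subset; inputs with fewer than
two effective dimensions return one component with a warning.

## Synthetic studies

The generator plants: gene-specific baselines ~ Uniform(4, 12) on the
log2 scale (a realistic microarray intensity range); disease blocks
shifted ±`effect_size` (default 2.5) in the disease arm; treatment arms
that restore a per-direction fraction of each disease block to the
healthy mean, flip a reversal fraction to the opposite sign (full
mirror), leave the rest at the diseased level, and displace an
arm-specific altered block; and i.i.d. Gaussian noise (default sd 0.25).
With these defaults the planted effect is ~10 standard errors at n = 10,
so detection is essentially saturated — deliberately, since the
reference design's strongly separated healthy/diseased profiles are the
regime of interest.

Which genes an arm fails to restore follows a shared per-gene difficulty
score with arm-specific jitter (sd 0.15 of the score range): arms restore
their easiest genes first, so not-restored sets of different arms overlap
heavily — as observed in real multi-arm studies — without being strictly
nested.  Independent per-arm sampling would make those overlaps
hypergeometric, which contradicts how restoration failure actually
concentrates on stubborn genes.

`reference_truth()` encodes the reference design: 404 over- / 463
under-expressed disease genes; five arms with not-restored counts
3 / 25 / 92 / 106 / 175 and altered blocks of 170 / 0 / 30 / 217 / 175
genes (the two largest sharing 40); group sizes 10 healthy, 13 diseased,
four therapeutic arms of 10 and one prophylactic arm of 3 (66 samples).
The prophylactic-like arm has the highest reversal fraction, mirroring
the over-compensation seen with early intervention.  The annotation
produced alongside contains the disease blocks, 3 + 5 sub-blocks, the
altered blocks, and 50 decoy categories of 10-200 random genes for
specificity checks.

What the generator does **not** emulate: mean–variance trends, batch or
array effects, correlated noise between genes, probe-level structure, and
partial (sub-threshold) restoration — treatments take only the three
planted levels.  Two consequences matter when interpreting green tests:
the extended and full-union sets coincide on synthetic data (no gene is
DE versus the disease control without also being DE versus healthy or
disease-associated), and detection is near-perfect rather than merely
good.  Passing the recovery suite therefore demonstrates correctness of
the pipeline's logic under its stated model, not robustness to real-data
pathology.

## Problem sizes used in the validation runs

The test suite runs the full pipeline at 2000 genes (the planted 1419
plus background) and the acceptance script at the full 18704 × 66
design; the repeated-forest loop uses 100 models in both (the
configuration default remains 1000, retained for full reproduction
runs).  The Dunnett Monte-Carlo oracle uses 10^6 draws; the type-I
calibration check uses 20 seeds × 2000 null genes on a 6 × 10 design.
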
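# Methods

`mmflowps` implements a response-classification and differential-expression
workflow for bulk RNA-seq cohorts of multiple-myeloma (MM) CD138+ samples
annotated with bortezomib-regimen response (good responders R = CR + VGPR,
poor responders NR = PR + MR). This note documents the statistical models,
the defaults and the design choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic cohorts

Counts are negative binomial with the `variance = mu + alpha * mu^2`
dispersion convention. Gene baseline abundances `base_g` are log-normal
(`baseline_log_mean = 3`, `baseline_log_sd = 1.5` on the natural-log scale,
spanning roughly four orders of magnitude, as in bulk RNA-seq). Sample j's
mean for gene g is

    mu_gj = libsize_j * base_g * 2^(effect_log2fc * dir_g * [g is marker, j is responder])

with `libsize_j` scaled so the expected column sum equals the sample's
simulated uniquely-mapped-read depth: log-normal around `mean_depth`
(default 8e6) with spread `libsize_log_sd = 0.35`, except planted
low-depth samples whose depth is uniform in [0.2M, 2.4M] — guaranteed to
fail the 2.5M uniquely-mapped-reads QC threshold. The default cohort shape
mirrors the MM study cohort: 53 samples at a 28:25 R:NR split, ~10^4 genes,
30 planted markers, regimen mix 33 VCD-only / 14 PAD+VCD / 6 PAD-only.
Binary labels derive from response categories (R samples drawn CR/VGPR
uniformly, NR samples PR/MR); only the binary label enters the analysis.

### Heterogeneity ("outlier subgroup")

`heterogeneity_fraction` draws a class-stratified subgroup of samples that
models a molecular subtype:

1. an additive +3 log2 shift on a fixed random 20% of genes, displacing the
   subgroup in expression space; and
2. an *inverted* marker-response association — up-in-R markers run down in
   subgroup responders.

This qualitative-interaction heterogeneity is the failure mode dynamic
training-set trimming targets: a single global model averages two opposed
label-feature relations and misclassifies the subgroup consistently,
whereas a sample-specific training window can fit each subtype locally.
Direction flips of MM response markers across cohorts (e.g. MAF has been
reported as a positive, neutral and negative predictor for
bortezomib-containing regimens in different datasets) motivate the
construct. Class stratification keeps subgroup membership orthogonal to
the label so the shifted genes cannot act as spurious markers. An earlier
design in which the subgroup simply carried *no* marker effect left global
fits essentially unharmed (LOO AUC >= 0.95) and gave trimming no headroom;
the inversion is what makes heterogeneity genuinely adversarial for a
global model.

What the generator does **not** model: batch effects, gene-gene
correlation beyond the subgroup block structure, isoform structure,
zero inflation, and sequencing-level artifacts. Passing benchmarks
therefore demonstrate correctness of the machinery and the qualitative
trimming benefit under NB sampling — not expected AUC levels on real
cohorts.

## QC and exploratory stage

Samples with fewer than 2.5 million uniquely mapped reads are dropped; the
boundary is inclusive ("at least" 2.5M). Exploratory clustering adds a +1
pseudocount, log2-transforms (flag-controlled; the pseudocount only
matters under a log), quantile-normalizes across samples (ties receive the
mean of the reference quantiles spanned by the tied block — the dominant
convention, stated here because implementations differ), and applies Ward
clustering on Euclidean sample distances in the variant whose update
operates on squared distances (scipy's `ward`, equivalent to R `ward.D2`
on unsquared distances). Distances use all genes; no variance pre-filter.
PCA is computed on centered data.

## Marker selection

Counts are normalized by median-of-ratios size factors: factor_j =
median over all-nonzero genes of counts_gj / geometric-mean_g. Note the
exact per-sample scaling identity holds at the level of size-factor
*ratios*: rescaling one sample rescales every geometric mean by c^(1/n),
so the normalized matrix changes by a single global constant (which no
downstream rank-based statistic sees).

Per-gene discrimination is the Mann-Whitney AUC (ties 1/2) of normalized
expression against the binary label, computed via average ranks. Because
markers can run in either direction, genes are ranked by the oriented AUC
max(a, 1-a) with the direction recorded; ties break lexicographically by
gene symbol so the selection is bit-reproducible. For each left-out sample
the top-30 list is recomputed on the remaining n-1 samples, and the **core
marker set** is the intersection of all n lists.

Two empirical properties of this procedure worth knowing:

- The intersection *stabilizes* but does not *null-calibrate*: LOO folds
  share n-2 samples, so genes that are extreme in the fixed sample survive
  every fold. Under a global null the core set is reduced but not empty
  (typically 10-16 genes of top-30 at n = 40). Core membership is
  therefore evidence of stability, not of significance.
- Because the final core set is selected on the full cohort, the
  subsequent LOO classification estimates carry selection optimism. This
  mirrors the published workflow; the with/without-FloWPS comparison is
  unaffected since both arms use the same features.

## FloWPS

For each test sample and each grid cell (k, m):

1. keep the top-m features of the cohort-level oriented-AUC ranking that
   survive the projective range filter (feature kept iff the test value
   lies within the training min/max); if none survive, fall back to the
   unfiltered top-m;
2. select the k nearest training samples (Euclidean distance over those
   features on per-fold z-scores; ties broken by sample order), expanding
   k minimally if the window lacks a class;
3. re-standardize the cell's features on the window and fit the base
   learner; score the test sample.

The final score is the unweighted mean over cells. Defaults: three k
values evenly spaced in [max(5, N/3), N] and m in {ceil(0.75 F), F} for F
core features. Two deliberate choices differ from the obvious
alternatives:

- **Cohort-level feature ranking, not per-fold.** Re-ranking inside each
  LOO fold looks leak-free but is anti-predictive: removing a sample that
  is discordant on a gene *raises* that gene's fold AUC, so the per-fold
  top-m preferentially selects genes on which the held-out sample is
  atypical for its class (measured: LOO ridge on per-fold top-3 core
  genes, AUC 0.32 vs 0.82 with the fixed ranking). The cohort-level
  ranking shares the core set's selection optimism identically across the
  trimmed and untrimmed arms.
- **m restricted to the top half of the core set.** The features entering
  FloWPS are already a stable LOO intersection; cells with m = 3 score far
  below baseline (per-cell LOO AUC 0.70-0.84 vs 0.95+) and dilute the
  unweighted mean. The window dimension k is where trimming earns its
  benefit. Both grids are config-overridable.

Window re-standardization makes binarize-at-0 naive Bayes meaningful
locally; on already-standardized input the degenerate full-window cell
reproduces the plain learner exactly, giving a clean reduction invariant.

## Classifiers and metrics

Five base learners with fixed settings: linear SVM (balanced class
weights), random forest (30 trees, entropy, balanced-subsample weights),
ridge regression (regularization 1.0, fit on +/-1 targets), Bernoulli
naive Bayes (smoothing 1.0, binarize at 0, uniform priors), MLP (one
hidden layer of 30 units, L2 penalty 1e-3). Features are z-scored per
training fold. Non-probabilistic outputs (SVM decision value, ridge
output) are mapped to [0, 1] by a logistic squash — monotone, so ROC AUC
and AUPR are unchanged; it only provides a common threshold scale.

Evaluation is leave-one-out; ROC AUC is the Mann-Whitney statistic and
AUPR the interpolation-free precision-recall step sum. The
sensitivity/specificity trade-off is swept by a false-positive vs
false-negative balance factor B through the threshold tau(B) = B/(1+B)
(B = 1 is the neutral 0.5 cut; the sweep default is 15 log-spaced values
in [0.1, 10]). The algebraic form of B is a documented stand-in chosen so
that B acts as a false-positive-cost multiplier; it is overridable.

## Differential expression and set overlaps

The DE test is an in-house per-gene NB Wald test (a DESeq2-style port with
shrinkage estimators is deliberately out of scope): group means on the
normalized scale, pooled method-of-moments dispersion floored at 1e-8, a
half-minimum pseudocount guarding zero group means, delta-method standard
error of the log2 mean ratio, two-sided normal p-values, BH adjustment.
Significance: adjusted p < 0.05 and |log2FC| > 0.5. Measured calibration
at 30 vs 30 samples: type-I error ~0.055 on a global null (the normal
reference is mildly liberal relative to a t with ~58 df), power ~1.0 for
log2FC = 3 at dispersion 0.1.

Overlap analysis: for D DEG sets over a universe of G genes, each of 1,000
permutations redraws every set's observed size uniformly without
replacement, yielding a null mean/sd and an add-one-corrected empirical p
per pair (expectation |A||B|/G), alongside Jaccard coefficients and
UpSet-style exclusive intersection counts on the real sets. The universe
defaults to all genes tested in at least one dataset and is a parameter.

## Problem sizes of the shipped benchmarks

The packaged experiments run: marker recovery at n = 60, 5,000 genes, 30
markers (log2FC 2, dispersion 0.1); the FloWPS comparison over 10
independent n = 60 cohorts of 1,000 genes (log2FC 1.5, dispersion 0.3,
30% subgroup) for all five methods; DE calibration on 2,000-gene nulls at
30 vs 30; and the overlap null at G = 3,000 with 1,000 permutations.
These sizes were chosen so a complete run finishes on a single CPU core in
minutes while keeping every Monte-Carlo tolerance meaningful.

## Known limitations

- Absolute AUC/AUPR levels on synthetic cohorts are not comparable to any
  real dataset: core-set selection optimism inflates them (see above), and
  the published grid/aggregation details of the original trimming method
  (its "tolerable parameter set" rule) are not public, so our grid is a
  documented reconstruction.
- The NB Wald test has no dispersion shrinkage; at very small n or very
  low counts it will be less stable than DESeq2-class estimators.
- Cross-dataset model transfer is out of scope (reported not to work for
  these cohorts), as are GO enrichment and microarray harmonization.
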
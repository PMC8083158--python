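# mmflowps

Response classification and differential expression for multiple-myeloma
RNA-seq cohorts treated with bortezomib-containing regimens (PAD / VCD).

Multiple myeloma patients respond very differently to bortezomib, and
cohorts small enough to be clinically realistic (tens of samples) are
too small for generic high-dimensional classifiers. This package
implements a pipeline built for exactly that setting, aimed at
computational biologists working with response-annotated count matrices:

- **QC and exploration** — mapped-reads filtering (>= 2.5M uniquely mapped
  reads per library), pseudocount + quantile normalization, Ward
  (`ward.D2`-style) hierarchical clustering and PCA of samples.
- **Core marker selection** — median-of-ratios size-factor normalization,
  per-gene Mann-Whitney AUC against the binary response label
  (R = CR+VGPR vs NR = PR+MR), and a leave-one-out stabilisation: the
  top-30 genes by oriented AUC, max(AUC, 1−AUC), are recomputed with each
  sample left out and intersected into a *core marker set* — the
  classifier feature space.
- **FloWPS** (floating-window projective separator) — dynamic,
  per-test-sample training-set trimming: features on which the test sample
  would extrapolate beyond the training range are dropped, the base
  learner is refitted on the k nearest training samples over a (k, m)
  parameter grid, and grid-cell scores are averaged.
- **Five classifiers** — linear SVM, random forest, ridge regression,
  Bernoulli naive Bayes and a multilayer perceptron with fixed,
  literature-standard hyperparameters — evaluated by leave-one-out ROC
  AUC / AUPR and sensitivity/specificity curves over a false-positive vs
  false-negative balance factor B (threshold τ(B) = B/(1+B)).
- **Differential expression and set overlaps** — a per-gene negative
  binomial Wald test (method-of-moments dispersion, BH adjustment,
  significance at adjusted p < 0.05 and |log2FC| > 0.5), and multi-dataset
  DEG-overlap analysis: observed pairwise intersections against a
  1,000-draw permutation null, Jaccard coefficients, UpSet counts.
- **Synthetic cohorts** — a first-class negative-binomial generator that
  emulates the structure of such studies (planted markers, library-size
  variation, QC-failing samples, an outlier subgroup that makes trimming
  matter), so the whole pipeline is testable without any download.

See `docs/methods.md` for the statistical details and design decisions.

## Worked example

```python
from mmflowps import (
    SimConfig, simulate_cohort, filter_by_mapped_reads,
    size_factor_normalize, loo_core_markers,
    ClassifierConfig, FlowpsParams, loo_evaluate,
)

cfg = SimConfig(n_samples=60, n_genes=2000, n_markers=30,
                effect_log2fc=1.5, dispersion=0.3, responder_fraction=0.5,
                heterogeneity_fraction=0.3, seed=0)
counts, annot, truth = simulate_cohort(cfg)
counts, annot, removed = filter_by_mapped_reads(counts, annot)

norm = size_factor_normalize(counts)
core = loo_core_markers(norm, annot["binary_label"], top_k=30)
print(f"core marker set: {len(core.genes)} genes")

features = norm.expression.loc[core.genes].T
params = FlowpsParams.default_grid(n_train=len(features) - 1,
                                   n_features=features.shape[1])
for method in ("ridge", "bnb"):
    config = ClassifierConfig(method=method, random_seed=0)
    plain = loo_evaluate(features, annot["binary_label"], config)
    trimmed = loo_evaluate(features, annot["binary_label"], config, params)
    print(f"{method}: LOO ROC AUC {plain.roc_auc:.3f} -> "
          f"{trimmed.roc_auc:.3f} with FloWPS")
```

Output:

```
core marker set: 16 genes
ridge: LOO ROC AUC 0.907 -> 0.946 with FloWPS
bnb: LOO ROC AUC 0.889 -> 0.958 with FloWPS
```

The cohort here contains a 30% "outlier subgroup" whose marker-response
association is inverted — heterogeneity that misleads a globally fitted
model. The LOO core set recovers a stable feature space, and FloWPS's
per-sample windows lift the out-of-fold AUC for both methods because each
test sample is scored by a model trained on its own neighborhood.

## Command line

The same stages are available as a CLI:

```sh
mmflowps simulate --out sim/ --n-samples 60 --seed 1
mmflowps qc --counts sim/counts.tsv --annotation sim/annotation.tsv --out qc/
mmflowps markers --counts qc/counts_qc.tsv --annotation qc/annotation_qc.tsv --out mk/
mmflowps classify --counts qc/counts_qc.tsv --annotation qc/annotation_qc.tsv \
    --genes mk/core_markers.tsv --out clf/
mmflowps run-all --config pipeline.yaml --out results/
```

`run-all` drives everything from one YAML config (simulation block or
input paths, cohort selector `full`/`VCD`, QC threshold, FloWPS grid,
methods, DE criteria, permutation count, one global seed) and writes a
manifest with the config hash for reproducibility.

## Using real data

`read_counts` / `read_annotation` accept tab-separated gene×sample count
matrices (HGNC symbols) and per-sample annotations (response category,
regimen, uniquely mapped reads, timepoint) — the layout of GEO series
GSE159426 (53 MM profiles, STAR GeneCounts) and GSE120795 (healthy CD138+
controls). Those series can be fetched manually or with GEOparse and fed
through the same pipeline; no stage depends on network access.
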
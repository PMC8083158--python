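"""Reproducible benchmark experiments over the synthetic study conditions.

These are the canonical end-to-end exercises of the pipeline: core-marker
recovery under strong planted signal, the FloWPS-benefit comparison on the
heterogeneous cohort, DE-test calibration (size and power) and the
overlap-permutation null check. Both the test suite and the reproduction
script run them, so the reported numbers always come from the same code
path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import METHODS, ClassifierConfig, loo_evaluate
from .degsets import nb_wald_de, pairwise_overlap_stats
from .flowps import FlowpsParams
from .markers import loo_core_markers, size_factor_normalize
from .simdata import SimConfig, simulate_cohort


def marker_recovery_experiment(
    seed: int = 1,
    n_samples: int = 60,
    n_genes: int = 5000,
    n_markers: int = 30,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    top_k: int = 30,
) -> dict:
    """Fraction of planted markers recovered in the LOO core set.

    Also verifies the structural invariant that the core is contained in
    every fold's top-k list.
    """
    cfg = SimConfig(
        n_samples=n_samples, n_genes=n_genes, n_markers=n_markers,
        effect_log2fc=effect_log2fc, dispersion=dispersion,
        responder_fraction=0.5, seed=seed,
    )
    counts, annot, truth = simulate_cohort(cfg)
    norm = size_factor_normalize(counts)
    core = loo_core_markers(norm, annot["binary_label"], top_k=top_k)
    recovered = len(set(core.genes) & set(truth.marker_genes)) / n_markers
    subset_ok = all(set(core.genes) <= set(f) for f in core.fold_lists.values())
    return {
        "recovery": recovered,
        "core_size": len(core.genes),
        "core_subset_of_every_fold": subset_ok,
        "n_samples": n_samples,
    }


#: heterogeneous-cohort study conditions for the FloWPS comparison:
#: a 60-sample cohort over 1,000 genes with 30 planted markers at
#: log2FC 1.5 (NB dispersion 0.3) and a 30% outlier subgroup.
HETEROGENEOUS_COHORT = dict(
    n_samples=60, n_genes=1000, n_markers=30, effect_log2fc=1.5,
    dispersion=0.3, responder_fraction=0.5, heterogeneity_fraction=0.3,
)


def flowps_benefit_experiment(
    seed: int = 0,
    n_seeds: int = 10,
    methods: tuple[str, ...] = METHODS,
    cohort_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Median LOO ROC AUC per method with and without FloWPS.

    Runs the full marker-selection + LOO-classification pipeline on
    ``n_seeds`` independent heterogeneous cohorts (seeds ``seed`` ..
    ``seed + n_seeds - 1``) and reports the per-method median AUCs and
    whether trimming was beneficial.
    """
    cohort_kwargs = {**HETEROGENEOUS_COHORT, **(cohort_kwargs or {})}
    per_seed: dict[str, list[tuple[float, float]]] = {m: [] for m in methods}
    for s in range(seed, seed + n_seeds):
        cfg = SimConfig(**cohort_kwargs, seed=s % (2**31))
        counts, annot, _ = simulate_cohort(cfg)
        norm = size_factor_normalize(counts)
        core = loo_core_markers(norm, annot["binary_label"], top_k=30)
        features = norm.expression.loc[core.genes].T
        params = FlowpsParams.default_grid(
            n_train=len(features) - 1, n_features=features.shape[1]
        )
        for m in methods:
            config = ClassifierConfig(method=m, random_seed=s % (2**31))
            plain = loo_evaluate(features, annot["binary_label"], config)
            trimmed = loo_evaluate(features, annot["binary_label"], config, params)
            per_seed[m].append((plain.roc_auc, trimmed.roc_auc))
    rows = []
    for m in methods:
        plain = float(np.median([p for p, _ in per_seed[m]]))
        trimmed = float(np.median([t for _, t in per_seed[m]]))
        rows.append(
            {
                "method": m,
                "median_auc": plain,
                "median_auc_flowps": trimmed,
                "flowps_beneficial": trimmed >= plain,
            }
        )
    return pd.DataFrame(rows).set_index("method")


def de_calibration_experiment(
    seed: int = 0,
    n_genes: int = 2000,
    n_per_group: int = 30,
    power_log2fc: float = 3.0,
) -> dict:
    """Type-I error on a global null and power on strong planted signal."""
    null_cfg = SimConfig(
        n_samples=2 * n_per_group, n_genes=n_genes, n_markers=0,
        effect_log2fc=0.0, dispersion=0.2, responder_fraction=0.5, seed=seed,
    )
    counts, annot, _ = simulate_cohort(null_cfg)
    norm = size_factor_normalize(counts)
    null_res = nb_wald_de(counts, annot["binary_label"], norm.size_factors)
    type1 = float((null_res.table["pvalue"] < 0.05).mean())

    power_cfg = SimConfig(
        n_samples=2 * n_per_group, n_genes=n_genes, n_markers=100,
        effect_log2fc=power_log2fc, dispersion=0.1, responder_fraction=0.5,
        seed=seed + 1,
    )
    counts, annot, truth = simulate_cohort(power_cfg)
    norm = size_factor_normalize(counts)
    res = nb_wald_de(counts, annot["binary_label"], norm.size_factors)
    power = float(
        len(set(res.significant) & set(truth.marker_genes)) / len(truth.marker_genes)
    )
    return {"type1_error": type1, "power": power, "n_genes": n_genes}


def overlap_null_experiment(
    seed: int = 0,
    universe_size: int = 3000,
    set_size: int = 30,
    n_perm: int = 1000,
) -> dict:
    """Permutation-null mean of a pairwise overlap vs the closed form."""
    rng = np.random.default_rng(seed)
    universe = [f"G{i:05d}" for i in range(universe_size)]
    sets = [
        set(rng.choice(universe, size=set_size, replace=False)) for _ in range(2)
    ]
    stats = pairwise_overlap_stats(sets, universe, n_perm=n_perm, seed=seed + 1)
    row = stats.pairs.iloc[0]
    return {
        "null_mean": float(row["null_mean"]),
        "expected": set_size * set_size / universe_size,
        "mc_se": float(row["null_sd"]) / np.sqrt(n_perm),
        "n_perm": n_perm,
    }
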
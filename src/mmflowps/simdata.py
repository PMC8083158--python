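"""Synthetic RNA-seq cohorts for the bortezomib-response pipeline.

The generator emulates the statistical structure of a CD138+ multiple-myeloma
RNA-seq cohort annotated with chemotherapy response: negative-binomial
gene-level counts over thousands of genes, two response classes (good
responders R = CR+VGPR vs poor responders NR = PR+MR) at roughly balanced
prevalence, log-normal library-size variation, a minority of low-depth
samples that fail the mapped-reads QC threshold, a planted set of
differentially expressed marker genes, and an optional "outlier subgroup"
of samples whose expression is shifted on a random block of genes —
the kind of cohort heterogeneity that dynamic training-set trimming
(FloWPS) is designed to cope with.

A second generator builds multi-dataset DEG-list scenarios (several gene
sets over a common universe sharing a planted core) for the overlap
permutation analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

#: mapped-read depth range (uniform) for planted QC-failing samples;
#: guaranteed below the 2.5M uniquely-mapped-reads threshold.
LOW_DEPTH_RANGE = (200_000, 2_400_000)

#: additive log2 shift applied to the outlier subgroup's shifted genes.
SUBGROUP_LOG2_SHIFT = 3.0

#: fraction of genes receiving the subgroup shift.
SUBGROUP_GENE_FRACTION = 0.2

RESPONDER_CATEGORIES = ("CR", "VGPR")
NONRESPONDER_CATEGORIES = ("PR", "MR")

#: regimen mix mirroring the study cohort (33 VCD-only, 14 PAD+VCD, 6 PAD-only of 53).
REGIMEN_PROBS = {"VCD": 33 / 53, "PAD+VCD": 14 / 53, "PAD": 6 / 53}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic response-annotated cohort.

    Defaults emulate the study cohort: 53 pretreatment profiles with a
    28:25 responder:non-responder split, ~10^4 genes, 30 planted marker
    genes, moderate NB dispersion and a median library depth of 8 million
    uniquely mapped reads.
    """

    n_samples: int = 53
    n_genes: int = 10_000
    n_markers: int = 30
    responder_fraction: float = 28 / 53
    effect_log2fc: float = 2.0
    dispersion: float = 0.15
    libsize_log_sd: float = 0.35
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    low_depth_fraction: float = 0.0
    heterogeneity_fraction: float = 0.0
    mean_depth: float = 8e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if self.n_markers < 0 or self.n_markers > self.n_genes:
            raise ValueError(
                f"n_markers must be in [0, n_genes]; got {self.n_markers} "
                f"with n_genes={self.n_genes}"
            )
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValueError(
                f"responder_fraction must be in (0, 1); got {self.responder_fraction}"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name in ("libsize_log_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("low_depth_fraction", "heterogeneity_fraction"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    marker_genes: dict[str, str] = field(default_factory=dict)  # gene -> "up"/"down" in R
    subgroup_assignment: dict[str, bool] = field(default_factory=dict)
    true_labels: dict[str, str] = field(default_factory=dict)  # sample -> "R"/"NR"
    low_depth_samples: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    # NB with variance mu + alpha*mu^2: shape r = 1/alpha, p = r/(r+mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a response-annotated NB count cohort.

    Returns ``(counts, annotation, truth)`` where ``counts`` is a genes x
    samples integer DataFrame, ``annotation`` a per-sample table with columns
    ``response_category``, ``binary_label``, ``regimen``,
    ``uniquely_mapped_reads`` and ``timepoint``, and ``truth`` records the
    planted markers, subgroup membership and labels.

    Gene means follow ``mu_gj = libsize_j * base_g * 2^(effect * dir_g)`` for
    marker genes in responders (non-markers share means across classes), with
    ``base_g`` log-normal and ``libsize_j`` scaled so the expected column sum
    matches the sample's simulated mapped-read depth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = np.array([f"GENE{i:05d}" for i in range(cfg.n_genes)])
    samples = np.array([f"S{j:03d}" for j in range(cfg.n_samples)])

    n_resp = int(round(cfg.responder_fraction * cfg.n_samples))
    n_resp = min(max(n_resp, 1), cfg.n_samples - 1)
    is_resp = np.zeros(cfg.n_samples, dtype=bool)
    is_resp[rng.choice(cfg.n_samples, size=n_resp, replace=False)] = True

    marker_idx = rng.choice(cfg.n_genes, size=cfg.n_markers, replace=False)
    marker_dir = rng.choice([1, -1], size=cfg.n_markers)  # +1 = up in responders

    base = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))

    # outlier subgroup — a molecular subtype with (a) an additive log2 shift
    # on a fixed random block of genes, displacing it in expression space,
    # and (b) an inverted marker-response association (up-in-R markers run
    # down in subgroup responders), the qualitative-interaction heterogeneity
    # reported for response markers across myeloma cohorts. A model fitted
    # globally misclassifies the subgroup consistently; sample-specific
    # trimming can fit each subtype locally. Membership is stratified by
    # class so subgroup structure stays orthogonal to the response label
    # (no spurious shift-gene markers).
    sub_samples = np.zeros(cfg.n_samples, dtype=bool)
    if cfg.heterogeneity_fraction > 0:
        for cls_mask in (is_resp, ~is_resp):
            idx = np.flatnonzero(cls_mask)
            n_cls = int(round(cfg.heterogeneity_fraction * len(idx)))
            if n_cls > 0:
                sub_samples[rng.choice(idx, size=n_cls, replace=False)] = True
    n_sub = int(sub_samples.sum())

    # class-dependent relative expression
    log2fc = np.zeros(cfg.n_genes)
    log2fc[marker_idx] = cfg.effect_log2fc * marker_dir
    rel = np.tile(base[:, None], (1, cfg.n_samples)).astype(float)
    rel[:, is_resp & ~sub_samples] *= 2.0 ** log2fc[:, None]
    rel[:, is_resp & sub_samples] *= 2.0 ** (-log2fc[:, None])

    if n_sub > 0:
        n_shift_genes = int(round(SUBGROUP_GENE_FRACTION * cfg.n_genes))
        shift_genes = rng.choice(cfg.n_genes, size=n_shift_genes, replace=False)
        shift = np.zeros(cfg.n_genes)
        shift[shift_genes] = SUBGROUP_LOG2_SHIFT
        rel[:, sub_samples] *= 2.0 ** shift[:, None]

    # mapped-read depths; planted low-depth samples fall below the QC threshold
    n_low = int(round(cfg.low_depth_fraction * cfg.n_samples))
    low = np.zeros(cfg.n_samples, dtype=bool)
    if n_low > 0:
        low[rng.choice(cfg.n_samples, size=n_low, replace=False)] = True
    depth = np.exp(
        rng.normal(
            np.log(cfg.mean_depth) - cfg.libsize_log_sd**2 / 2.0,
            cfg.libsize_log_sd,
            cfg.n_samples,
        )
    )
    depth[low] = rng.uniform(*LOW_DEPTH_RANGE, size=n_low)

    libsize = depth / rel.sum(axis=0)
    mu = rel * libsize[None, :]
    counts = _nb_draws(rng, mu, cfg.dispersion)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene"

    categories = np.where(
        is_resp,
        rng.choice(RESPONDER_CATEGORIES, size=cfg.n_samples),
        rng.choice(NONRESPONDER_CATEGORIES, size=cfg.n_samples),
    )
    regimens = rng.choice(
        list(REGIMEN_PROBS), size=cfg.n_samples, p=list(REGIMEN_PROBS.values())
    )
    annot = pd.DataFrame(
        {
            "sample_id": samples,
            "response_category": categories,
            "binary_label": np.where(is_resp, "R", "NR"),
            "regimen": regimens,
            "uniquely_mapped_reads": counts_df.sum(axis=0).to_numpy(),
            "timepoint": "pretreatment",
        }
    ).set_index("sample_id")

    truth = SyntheticTruth(
        marker_genes={
            genes[g]: ("up" if d > 0 else "down")
            for g, d in zip(marker_idx, marker_dir)
        },
        subgroup_assignment={s: bool(f) for s, f in zip(samples, sub_samples)},
        true_labels={s: ("R" if f else "NR") for s, f in zip(samples, is_resp)},
        low_depth_samples=[s for s, f in zip(samples, low) if f],
    )
    return counts_df, annot, truth


def simulate_deg_universe(
    n_datasets: int,
    universe_size: int,
    set_sizes: list[int] | int,
    shared_core_size: int,
    seed: int,
) -> tuple[list[set[str]], dict]:
    """Simulate per-dataset DEG lists sharing a planted core.

    Each dataset's set is the shared core plus uniformly drawn non-core
    genes from a common universe. Returns the list of gene sets plus a truth
    dict with the universe, the core genes and whether pairwise overlaps are
    enriched over the random expectation.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if isinstance(set_sizes, int):
        set_sizes = [set_sizes] * n_datasets
    if len(set_sizes) != n_datasets:
        raise ValueError("set_sizes must have one entry per dataset")
    if shared_core_size > min(set_sizes):
        raise ValueError("shared_core_size must be <= min(set_sizes)")
    if max(set_sizes) > universe_size:
        raise ValueError("set sizes cannot exceed universe_size")

    rng = np.random.default_rng(seed)
    universe = np.array([f"GENE{i:05d}" for i in range(universe_size)])
    core_idx = rng.choice(universe_size, size=shared_core_size, replace=False)
    core = set(universe[core_idx])
    non_core = np.setdiff1d(np.arange(universe_size), core_idx)

    sets: list[set[str]] = []
    for size in set_sizes:
        extra = rng.choice(non_core, size=size - shared_core_size, replace=False)
        sets.append(core | set(universe[extra]))

    truth = {
        "universe": list(universe),
        "core_genes": sorted(core),
        "overlaps_enriched": shared_core_size > 0,
    }
    return sets, truth


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t")
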
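"""Negative-binomial differential expression and multi-dataset DEG-overlap
analysis.

The DE test is a per-gene NB Wald test on size-factor-normalized counts:
group means are compared on the log2 scale, the gene's dispersion alpha
(variance = mu + alpha*mu^2) is estimated by pooled method of moments and
floored at 1e-8, and the delta-method standard error of the log2 mean ratio
feeds a two-sided normal Wald p-value. P-values are Benjamini-Hochberg
adjusted across all tested genes, and a gene is flagged significant iff
adjusted p < 0.05 and |log2FC| > 0.5.

The overlap analysis takes DEG sets from several datasets over a common
gene universe and asks whether their pairwise intersections exceed the
random expectation: for each of 1,000 permutations every dataset redraws
its observed number of genes uniformly from the universe, giving a null
mean/sd and an empirical p per pair, alongside Jaccard coefficients and
UpSet-style exclusive intersection counts on the real sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PADJ_CUTOFF = 0.05
LFC_CUTOFF = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass
class DegResult:
    """Per-gene DE table plus the genes skipped as all-zero."""

    table: pd.DataFrame
    skipped_genes: list[str]

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def nb_wald_de(
    counts: pd.DataFrame,
    labels: pd.Series,
    size_factors: pd.Series,
    padj_cutoff: float = PADJ_CUTOFF,
    lfc_cutoff: float = LFC_CUTOFF,
) -> DegResult:
    """NB Wald differential expression, responders (R) vs non-responders (NR).

    ``counts`` is genes x samples raw counts; ``size_factors`` the
    median-of-ratios factors. log2FC is the log2 ratio of group means on the
    normalized scale, with a half-minimum pseudocount guarding zero means.
    All-zero genes are skipped and reported.
    """
    labels = pd.Series(np.asarray(labels), index=counts.columns)
    pos = (labels == "R").to_numpy()
    neg = (labels == "NR").to_numpy()
    if pos.sum() < 3 or neg.sum() < 3:
        raise ValueError("need at least 3 samples per class")

    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    nonzero = norm.sum(axis=1) > 0
    skipped = counts.index[~nonzero].tolist()
    y = norm[nonzero]
    genes = counts.index[nonzero]

    y1, y0 = y[:, pos], y[:, neg]
    n1, n0 = y1.shape[1], y0.shape[1]
    m1, m0 = y1.mean(axis=1), y0.mean(axis=1)
    v1 = y1.var(axis=1, ddof=1)
    v0 = y0.var(axis=1, ddof=1)

    # pooled method-of-moments dispersion: var = mu + alpha mu^2 within groups
    pooled_mu = (n1 * m1 + n0 * m0) / (n1 + n0)
    pooled_var = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mu) / pooled_mu**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    # half-minimum pseudocount on normalized means guards zero groups
    positive_means = np.concatenate([m1[m1 > 0], m0[m0 > 0]])
    eps = 0.5 * positive_means.min() if len(positive_means) else 0.5
    log2fc = np.log2((m1 + eps) / (m0 + eps))

    # delta method on log(mean): Var(log m_k) ~ (mu + alpha mu^2) / (n_k mu^2)
    var_log1 = (m1 + eps + alpha * (m1 + eps) ** 2) / (n1 * (m1 + eps) ** 2)
    var_log0 = (m0 + eps + alpha * (m0 + eps) ** 2) / (n0 * (m0 + eps) ** 2)
    se_log2 = np.sqrt(var_log1 + var_log0) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se_log2
    pvals = 2.0 * stats.norm.sf(np.abs(wald))

    padj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "base_mean": pooled_mu,
            "log2fc": log2fc,
            "dispersion": alpha,
            "wald_stat": wald,
            "pvalue": pvals,
            "padj": padj,
            "direction": np.where(log2fc >= 0, "+", "-"),
        },
        index=pd.Index(genes, name="gene"),
    )
    table["significant"] = (table["padj"] < padj_cutoff) & (
        table["log2fc"].abs() > lfc_cutoff
    )
    return DegResult(table=table, skipped_genes=skipped)


def count_pairs(n_sets: int) -> int:
    """Number of unordered dataset pairs, n(n-1)/2."""
    if n_sets < 2:
        raise ValueError("need at least 2 sets")
    return n_sets * (n_sets - 1) // 2


def jaccard(set_a: set, set_b: set) -> float:
    """|A∩B| / |A∪B|; 0 for two empty sets."""
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


@dataclass
class OverlapStats:
    """Observed-vs-expected pairwise overlaps under a random-draw null."""

    pairs: pd.DataFrame  # per pair: observed, null_mean, null_sd, z, p, jaccard
    shared_genes: dict[tuple[int, int], list[str]]
    upset: pd.DataFrame
    n_perm: int

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def pairwise_overlap_stats(
    deg_sets: list[set[str]],
    universe: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    directions: list[dict[str, str]] | None = None,
) -> OverlapStats:
    """Pairwise overlap of DEG sets against a uniform-redraw permutation null.

    For each permutation, every dataset redraws its observed number of genes
    uniformly without replacement from the universe, and all pairwise
    intersection sizes are recorded. The empirical p per pair is the
    add-one-corrected fraction of permutations with an intersection at least
    as large as observed; Jaccard coefficients and shared-gene identities
    (with DE directions when supplied) refer to the real sets.
    """
    universe_arr = np.asarray(universe)
    universe_set = set(universe_arr.tolist())
    for i, s in enumerate(deg_sets):
        stray = set(s) - universe_set
        if stray:
            raise ValueError(
                f"set {i} contains genes outside the universe: {sorted(stray)[:5]}"
            )
    n_sets = len(deg_sets)
    if n_sets < 2:
        raise ValueError("need at least 2 sets")
    G = len(universe_arr)
    sizes = [len(s) for s in deg_sets]
    pair_list = list(combinations(range(n_sets), 2))

    rng = np.random.default_rng(seed)
    null_counts = np.empty((n_perm, len(pair_list)), dtype=np.int64)
    for p in range(n_perm):
        draws = [
            np.zeros(G, dtype=bool) for _ in range(n_sets)
        ]
        for d in range(n_sets):
            draws[d][rng.choice(G, size=sizes[d], replace=False)] = True
        for idx, (a, b) in enumerate(pair_list):
            null_counts[p, idx] = np.count_nonzero(draws[a] & draws[b])

    rows = []
    shared: dict[tuple[int, int], list[str]] = {}
    for idx, (a, b) in enumerate(pair_list):
        inter = deg_sets[a] & deg_sets[b]
        observed = len(inter)
        null = null_counts[:, idx]
        null_sd = float(null.std(ddof=1))
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "observed": observed,
                "null_mean": float(null.mean()),
                "null_sd": null_sd,
                "z": (observed - null.mean()) / null_sd if null_sd > 0 else np.inf,
                "p_empirical": (np.count_nonzero(null >= observed) + 1)
                / (n_perm + 1),
                "jaccard": jaccard(deg_sets[a], deg_sets[b]),
            }
        )
        if directions is not None:
            shared[(a, b)] = sorted(
                f"{g} ({directions[a].get(g, '?')}/{directions[b].get(g, '?')})"
                for g in inter
            )
        else:
            shared[(a, b)] = sorted(inter)

    return OverlapStats(
        pairs=pd.DataFrame(rows),
        shared_genes=shared,
        upset=upset_counts(deg_sets),
        n_perm=n_perm,
    )


def upset_counts(deg_sets: list[set[str]]) -> pd.DataFrame:
    """Exclusive intersection sizes per non-empty dataset combination.

    Each gene in the union is assigned to exactly the combination of sets it
    belongs to, so the counts partition the union.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least 2 sets")
    union = sorted(set().union(*deg_sets))
    membership: dict[tuple[int, ...], int] = {}
    for gene in union:
        combo = tuple(i for i, s in enumerate(deg_sets) if gene in s)
        membership[combo] = membership.get(combo, 0) + 1
    rows = [
        {"combination": combo, "degree": len(combo), "count": count}
        for combo, count in sorted(membership.items())
    ]
    return pd.DataFrame(rows)
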
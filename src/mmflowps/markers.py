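"""Median-of-ratios normalization and LOO core marker-gene selection.

The classifier feature space is built in three steps: (i) size-factor
normalization of raw counts by the median-of-ratios method, (ii) per-gene
ROC AUC of normalized expression against the binary responder label, and
(iii) leave-one-out stabilisation — the top-k (default 30) genes by
direction-agnostic ("oriented") AUC are recomputed with each sample left
out in turn, and the core marker set is the intersection of all n top-k
lists.

AUC here is the Mann-Whitney probability that a random responder value
exceeds a random non-responder value, with ties counted 1/2; the oriented
AUC max(a, 1-a) treats up- and down-regulated markers symmetrically and its
direction records which way the gene moves in responders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized expression (genes x samples)."""

    expression: pd.DataFrame
    size_factors: pd.Series
    reference_genes: list[str]


@dataclass
class CoreMarkerSet:
    """Per-fold top-k marker lists and their intersection."""

    top_k: int
    fold_lists: dict[str, list[str]]  # left-out sample id -> top-k genes
    core_genes: pd.DataFrame  # index gene; columns: direction, presence_count
    ranking: pd.DataFrame = field(repr=False, default=None)  # full-cohort ranking

    @property
    def genes(self) -> list[str]:
        return list(self.core_genes.index)

    def to_tsv(self, path) -> None:
        self.core_genes.to_csv(path, sep="\t")


def size_factor_normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    """Median-of-ratios normalization.

    The size factor of sample j is the median over reference genes (genes
    with nonzero counts in every sample) of counts_gj / geomean_g, where
    geomean_g is the across-sample geometric mean of gene g. Normalized
    expression is counts divided column-wise by the size factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    values = counts.to_numpy(dtype=float)
    all_nonzero = (values > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "add a pseudocount or filter samples first"
        )
    ref = values[all_nonzero]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    return NormalizedMatrix(
        expression=counts / sf,
        size_factors=sf,
        reference_genes=list(counts.index[all_nonzero]),
    )


def _as_binary(labels: pd.Series | np.ndarray, index=None) -> np.ndarray:
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if not classes <= {"R", "NR"}:
        raise ValueError(f"labels must be R/NR; got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both classes (R and NR) must be present")
    return labels == "R"


def gene_auc(values, labels) -> float:
    """Mann-Whitney AUC of one gene's values for R (positive) vs NR, ties 1/2."""
    return float(auc_matrix(np.asarray(values, dtype=float)[None, :], labels)[0])


def auc_matrix(values: np.ndarray, labels) -> np.ndarray:
    """Row-wise Mann-Whitney AUC of a genes x samples matrix against R/NR labels."""
    pos = _as_binary(labels)
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    ranks = rankdata(values, axis=1)
    rank_sum = ranks[:, pos].sum(axis=1)
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def rank_markers(norm: NormalizedMatrix | pd.DataFrame, labels) -> pd.DataFrame:
    """Rank genes by oriented AUC (descending; ties broken by gene symbol).

    Returns a DataFrame indexed by gene with columns ``raw_auc``,
    ``oriented_auc``, ``direction`` (up_in_R iff raw_auc >= 0.5) and ``rank``.
    """
    expr = norm.expression if isinstance(norm, NormalizedMatrix) else norm
    raw = auc_matrix(expr.to_numpy(dtype=float), labels)
    table = pd.DataFrame(
        {
            "raw_auc": raw,
            "oriented_auc": np.maximum(raw, 1.0 - raw),
            "direction": np.where(raw >= 0.5, "up_in_R", "down_in_R"),
        },
        index=expr.index,
    )
    # descending oriented AUC, lexicographic gene symbol on ties (reproducible)
    order = np.lexsort((table.index.to_numpy(), -table["oriented_auc"].to_numpy()))
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def loo_core_markers(
    norm: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    top_k: int = 30,
) -> CoreMarkerSet:
    """Leave-one-out core marker selection.

    For each sample i, the top-k genes by oriented AUC are computed on the
    remaining n-1 samples; the core set is the intersection of all n lists.
    Directions are taken from the full-cohort ranking.
    """
    expr = norm.expression if isinstance(norm, NormalizedMatrix) else norm
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    counts_per_class = labels.value_counts()
    if counts_per_class.min() < 3:
        raise ValueError("need at least 3 samples per class for LOO selection")

    full_ranking = rank_markers(expr, labels)
    fold_lists: dict[str, list[str]] = {}
    presence: dict[str, int] = {}
    for sample in expr.columns:
        mask = expr.columns != sample
        fold_rank = rank_markers(expr.loc[:, mask], labels[mask])
        top = fold_rank.index[:top_k].tolist()
        fold_lists[sample] = top
        for g in top:
            presence[g] = presence.get(g, 0) + 1

    core = sorted(g for g, c in presence.items() if c == len(expr.columns))
    core_df = pd.DataFrame(
        {
            "direction": full_ranking.loc[core, "direction"],
            "presence_count": [presence[g] for g in core],
        },
        index=pd.Index(core, name="gene"),
    )
    return CoreMarkerSet(
        top_k=top_k, fold_lists=fold_lists, core_genes=core_df, ranking=full_ranking
    )


def target_gene_report(
    norm: NormalizedMatrix,
    genes: list[str],
    annot: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample normalized expression of selected genes plus their oriented AUC.

    AUC is computed over pretreatment samples carrying a binary responder
    label; relapse samples are included in the expression table (annotated by
    timepoint) so paired pretreatment/relapse changes can be read off.
    """
    missing = sorted(set(genes) - set(norm.expression.index))
    if missing:
        raise ValueError(f"unknown gene symbol(s): {', '.join(missing)}")
    expr = norm.expression.loc[genes]
    table = expr.T.join(annot[["response_category", "binary_label", "timepoint"]])

    eligible = annot.index[
        (annot["timepoint"] == "pretreatment") & annot["binary_label"].isin(["R", "NR"])
    ]
    sub = expr.loc[:, eligible]
    raw = auc_matrix(sub.to_numpy(dtype=float), annot.loc[eligible, "binary_label"])
    oriented = pd.Series(np.maximum(raw, 1 - raw), index=genes, name="oriented_auc")
    return table, oriented
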
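"""Count-matrix I/O, mapped-reads QC and exploratory clustering/PCA.

Count matrices are plain pandas DataFrames (genes x samples, HGNC-symbol
index); sample annotations are DataFrames indexed by sample id with the
response category, the derived binary responder label, the regimen, the
uniquely-mapped-read depth and the timepoint. Reading validates both and
fails loudly on duplicated identifiers, negative or non-integer counts and
matrix/annotation mismatches.

The QC stage drops samples below a uniquely-mapped-reads threshold
(2.5 million by default, boundary inclusive). The exploratory stage offers
pseudocount + quantile normalization, Ward hierarchical clustering on
Euclidean sample distances (the "ward.D2" convention: the update operates
on squared distances) and a PCA embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from skbio import TreeNode

QC_READ_THRESHOLD = 2_500_000

ANNOTATION_COLUMNS = (
    "response_category",
    "regimen",
    "uniquely_mapped_reads",
    "timepoint",
)

_RESPONDER = {"CR", "VGPR"}
_NONRESPONDER = {"PR", "MR"}
_CATEGORIES = _RESPONDER | _NONRESPONDER | {"healthy"}


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dupes = sorted(labels[labels.duplicated()].unique())
        raise ValueError(f"duplicated {what}: {', '.join(map(str, dupes))}")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples count matrix (unique labels, non-negative integers)."""
    _check_unique(counts.index, "gene symbol(s)")
    _check_unique(counts.columns, "sample id(s)")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts must be numeric")
    if (values < 0).any():
        bad = counts.index[(values < 0).any(axis=1)][:5].tolist()
        raise ValueError(f"negative counts in genes: {bad}")
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers (raw counts, not normalized values)")
    return counts.astype(np.int64)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated gene x sample raw count matrix (first column = gene symbol)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene"
    return validate_counts(counts)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated sample annotation table indexed by ``sample_id``."""
    annot = pd.read_csv(path, sep="\t")
    if "sample_id" not in annot.columns:
        raise ValueError("annotation is missing required column: sample_id")
    annot = annot.set_index("sample_id")
    return validate_annotation(annot)


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation is missing required column(s): {', '.join(missing)}")
    _check_unique(annot.index, "sample id(s)")
    bad = set(annot["response_category"]) - _CATEGORIES
    if bad:
        raise ValueError(f"unknown response categories: {sorted(bad)}")
    if (annot["uniquely_mapped_reads"] < 0).any():
        raise ValueError("uniquely_mapped_reads must be non-negative")
    annot = annot.copy()
    annot["binary_label"] = derive_binary_label(annot["response_category"])
    return annot


def derive_binary_label(categories: pd.Series) -> pd.Series:
    """R for CR/VGPR, NR for PR/MR, none for healthy controls."""
    return categories.map(
        lambda c: "R" if c in _RESPONDER else ("NR" if c in _NONRESPONDER else "none")
    )


def align(counts: pd.DataFrame, annot: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check matrix and annotation cover the same samples; align column order."""
    missing = sorted(set(counts.columns) - set(annot.index))
    if missing:
        raise ValueError(f"annotation missing for sample(s): {', '.join(missing)}")
    extra = sorted(set(annot.index) - set(counts.columns))
    if extra:
        raise ValueError(f"annotated sample(s) absent from matrix: {', '.join(extra)}")
    return counts, annot.loc[counts.columns]


def filter_by_mapped_reads(
    counts: pd.DataFrame,
    annot: pd.DataFrame,
    threshold: int = QC_READ_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Drop samples with fewer than ``threshold`` uniquely mapped reads.

    The boundary is inclusive: a sample with exactly ``threshold`` reads is
    retained. Returns the filtered matrix, the filtered annotation and the
    list of removed sample ids.
    """
    counts, annot = align(counts, annot)
    keep = annot["uniquely_mapped_reads"] >= threshold
    removed = annot.index[~keep].tolist()
    return counts.loc[:, keep.to_numpy()], annot.loc[keep], removed


def quantile_normalize_with_pseudocount(
    counts: pd.DataFrame,
    pseudocount: float = 1.0,
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Pseudocount, optional log2, then quantile normalization across samples.

    After normalization every sample shares the same sorted value vector (the
    row-wise mean of the sorted columns); ties within a sample receive the
    mean of the reference quantiles spanned by the tied block.
    """
    if counts.shape[1] == 0:
        raise ValueError("empty matrix")
    values = counts.to_numpy(dtype=float) + pseudocount
    if log2_transform:
        values = np.log2(values)
    if counts.shape[1] == 1:
        warnings.warn("single-sample input: quantile normalization is the identity")
        return pd.DataFrame(values, index=counts.index, columns=counts.columns)

    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col_sorted = values[order[:, j], j]
        assigned = reference.copy()
        # average reference values over blocks of tied input values
        block_starts = np.flatnonzero(np.r_[True, np.diff(col_sorted) != 0])
        block_ends = np.r_[block_starts[1:], len(col_sorted)]
        for s, e in zip(block_starts, block_ends):
            if e - s > 1:
                assigned[s:e] = reference[s:e].mean()
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


@dataclass
class Dendrogram:
    """Agglomerative clustering result over samples.

    ``linkage_matrix`` is the scipy linkage encoding (merge pairs in the
    first two columns, non-decreasing merge heights in the third).
    """

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        assignment = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return pd.Series(assignment, index=self.labels, name="cluster")

    def to_newick(self, path: str | Path | None = None) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        newick = str(tree)
        if path is not None:
            Path(path).write_text(newick)
        return newick


def hierarchical_cluster(values: pd.DataFrame) -> Dendrogram:
    """Ward clustering of samples on Euclidean distances (ward.D2 convention).

    ``values`` is a genes x samples matrix of (normalized) expression;
    samples are the clustered observations.
    """
    if values.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    data = values.to_numpy(dtype=float).T
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in expression matrix")
    link = linkage(data, method="ward", metric="euclidean")
    return Dendrogram(linkage_matrix=link, labels=list(values.columns))


def pca_embed(
    values: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on centered expression; returns coordinates and
    explained-variance fractions."""
    n_samples = values.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > min(values.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_genes, n_samples)="
            f"{min(values.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(values.to_numpy(dtype=float).T)
    coords_df = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return coords_df, pca.explained_variance_ratio_
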
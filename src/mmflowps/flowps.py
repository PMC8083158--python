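"""FloWPS: floating-window projective separator (dynamic data trimming).

For every test sample FloWPS builds a sample-specific training set before a
base classifier is fitted:

1. *Projective feature filtering* — drop every feature on which the test
   value lies outside the training min/max range, so the fitted model never
   extrapolates in feature space.
2. *Floating window* — keep only the k training samples nearest the test
   sample (Euclidean distance over the retained features), as in kNN, so
   distant and potentially confounding training points do not shape the
   decision boundary.

Both steps are swept over a (k, m) grid — k window sizes by m top-ranked
feature counts — the base learner is refitted in each grid cell, and the
test sample's final score is the unweighted mean of the per-cell scores.
A window that lacks one of the two classes is minimally enlarged until both
are present so that every cell stays fittable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FlowpsParams:
    """(k, m) grid for FloWPS.

    k values are window sizes (2 <= k <= number of training samples); m
    values are counts of top-ranked features. The default grid puts the
    trimming work on the window dimension — ~3 evenly spaced k from
    max(5, ceil(N/3)) to N — and sweeps m only over the top half of the
    feature list ({ceil(3|F|/4), |F|}): the features entering FloWPS are
    already a stable LOO-intersected core set, and cutting deeper than half
    of it discards consistently informative genes and degrades every base
    learner. Scores are aggregated by an unweighted mean over cells.
    """

    k_grid: list[int] = field(default_factory=list)
    m_grid: list[int] = field(default_factory=list)

    @classmethod
    def default_grid(
        cls, n_train: int, n_features: int, n_values: int = 3
    ) -> "FlowpsParams":
        k_lo = max(5, int(np.ceil(n_train / 3)))
        k_lo = min(k_lo, n_train)
        k_grid = sorted(set(np.linspace(k_lo, n_train, n_values).round().astype(int)))
        m_grid = sorted({int(np.ceil(0.75 * n_features)), n_features})
        return cls(k_grid=[int(k) for k in k_grid], m_grid=[int(m) for m in m_grid])

    def validate(self, n_train: int, n_features: int) -> None:
        if not self.k_grid or not self.m_grid:
            raise ValueError("k_grid and m_grid must be non-empty")
        if max(self.k_grid) > n_train or min(self.k_grid) < 2:
            raise ValueError(f"k values must lie in [2, {n_train}]")
        if max(self.m_grid) > n_features or min(self.m_grid) < 1:
            raise ValueError(f"m values must lie in [1, {n_features}]")


@dataclass
class TrimmedTrainingSet:
    """Provenance of one grid cell's trimmed training set."""

    retained_features: list[int]
    neighbor_ids: list[int]
    k: int
    m: int
    range_filter_applied: bool


def projective_feature_filter(
    test_vector: np.ndarray, training_matrix: np.ndarray
) -> np.ndarray:
    """Indices of features whose training range contains the test value.

    ``training_matrix`` is samples x features; feature f is retained iff
    min_train(f) <= test(f) <= max_train(f).
    """
    test_vector = np.asarray(test_vector, dtype=float)
    training_matrix = np.asarray(training_matrix, dtype=float)
    lo = training_matrix.min(axis=0)
    hi = training_matrix.max(axis=0)
    keep = (test_vector >= lo) & (test_vector <= hi)
    return np.flatnonzero(keep)


def select_window(
    test_vector: np.ndarray,
    training_matrix: np.ndarray,
    k: int,
    labels: np.ndarray | None = None,
    feature_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the k training samples nearest the test sample.

    Euclidean distance over ``feature_subset`` (all features by default);
    ties are broken by training-sample order. When ``labels`` is given and
    the window contains a single class, k is minimally enlarged until both
    classes are present.
    """
    training_matrix = np.asarray(training_matrix, dtype=float)
    test_vector = np.asarray(test_vector, dtype=float)
    n_train = training_matrix.shape[0]
    if k > n_train:
        raise ValueError(f"k={k} exceeds the {n_train} training samples")
    if feature_subset is not None:
        if len(feature_subset) == 0:
            raise ValueError("feature_subset must be non-empty")
        training_matrix = training_matrix[:, feature_subset]
        test_vector = test_vector[feature_subset]

    dist = np.linalg.norm(training_matrix - test_vector[None, :], axis=1)
    order = np.lexsort((np.arange(n_train), dist))  # stable: sample order on ties

    if labels is not None:
        labels = np.asarray(labels)
        if len(set(labels[order].tolist())) < 2:
            raise ValueError("training set contains a single class")
        while len(set(labels[order[:k]].tolist())) < 2:
            k += 1
    return np.sort(order[:k])


def flowps_predict(
    test_vector: np.ndarray,
    training_matrix: np.ndarray,
    training_labels: np.ndarray,
    base_learner,
    params: FlowpsParams,
    feature_ranking: np.ndarray,
    collect_provenance: bool = False,
):
    """Score one test sample by grid-averaged trimmed fits of the base learner.

    ``training_matrix`` is samples x features (already on a comparable
    per-feature scale, e.g. training-fold z-scores); ``feature_ranking`` lists
    feature indices from most to least informative (e.g. by training-fold
    oriented AUC). For every (k, m) cell the learner is refitted on the
    window of the k nearest neighbors restricted to the top-m ranked features
    that survive the projective range filter, and the final score is the mean
    of the per-cell scores. Each cell's features are re-standardized on its
    own window before fitting (learners that binarize or regularize around
    zero need the local center); on already-standardized input the degenerate
    full-window/full-feature cell therefore reproduces the plain learner
    exactly. If the filter removes all of a cell's features,
    that cell falls back to the unfiltered top-m features; if every cell is
    unusable the plain untrimmed learner is used (with a warning).

    Returns the score, or ``(score, provenance)`` when ``collect_provenance``.
    """
    X = np.asarray(training_matrix, dtype=float)
    y = np.asarray(training_labels)
    x = np.asarray(test_vector, dtype=float)
    n_train, n_features = X.shape
    params.validate(n_train, n_features)
    ranking = np.asarray(feature_ranking)

    surviving = projective_feature_filter(x, X)
    surviving_set = set(surviving.tolist())

    scores: list[float] = []
    provenance: list[TrimmedTrainingSet] = []
    for m in params.m_grid:
        top_m = ranking[:m]
        feats = np.array([f for f in top_m if f in surviving_set], dtype=int)
        range_filtered = True
        if len(feats) == 0:
            # documented fallback: keep the top-m ranked features unfiltered
            feats = np.asarray(top_m, dtype=int)
            range_filtered = False
        for k in params.k_grid:
            try:
                window = select_window(x, X, k, labels=y, feature_subset=feats)
            except ValueError:
                logger.debug("skipping cell (k=%d, m=%d): no usable window", k, m)
                continue
            # re-standardize within the window: learners that binarize or
            # regularize around 0 need the local (not fold-wide) feature center
            Xw = X[np.ix_(window, feats)]
            mu = Xw.mean(axis=0)
            sd = Xw.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            learner = base_learner.fresh()
            learner.fit((Xw - mu) / sd, y[window])
            scores.append(float(learner.score_one((x[feats] - mu) / sd)))
            if collect_provenance:
                provenance.append(
                    TrimmedTrainingSet(
                        retained_features=feats.tolist(),
                        neighbor_ids=window.tolist(),
                        k=k,
                        m=m,
                        range_filter_applied=range_filtered,
                    )
                )

    if not scores:
        warnings.warn(
            "all FloWPS grid cells were unusable; falling back to the "
            "untrimmed training set"
        )
        learner = base_learner.fresh()
        learner.fit(X, y)
        score = float(learner.score_one(x))
    else:
        score = float(np.mean(scores))
    if collect_provenance:
        return score, provenance
    return score
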
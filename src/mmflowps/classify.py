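"""Five base classifiers, leave-one-out evaluation (with/without FloWPS)
and threshold-sweep metrics.

The five methods and their fixed hyperparameters: linear SVM
(class_weight='balanced'), random forest (30 trees, entropy criterion,
class_weight='balanced_subsample'), ridge (Tikhonov) regression
(regularization strength 1.0), binomial/Bernoulli naive Bayes (additive
smoothing 1.0, binarization threshold 0.0, uniform class priors) and a
multilayer perceptron (one hidden layer of 30 units, L2 penalty 0.001).
Features are z-scored per training fold before fitting — this is what makes
the naive-Bayes binarize-at-0 semantics meaningful and conditions the MLP.

Every learner emits a score in [0, 1]: the positive-class probability where
the method defines one, otherwise (SVM decision value, ridge output on +/-1
targets) a logistic squashing 1/(1+exp(-x)) of the raw output — a monotone
map, so ROC AUC and AUPR are unaffected.

Sensitivity/specificity are swept over a false-positive vs false-negative
balance factor B via the threshold tau(B) = B/(1+B): B = 1 recovers the
neutral 0.5 cut, small B favours sensitivity, large B favours specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Ridge
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.naive_bayes import BernoulliNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.exceptions import ConvergenceWarning

from .flowps import FlowpsParams, flowps_predict
from .markers import auc_matrix

METHODS = ("svm", "rf", "ridge", "bnb", "mlp")

#: 15 log-spaced balance-factor values in [0.1, 10]
DEFAULT_B_GRID = np.logspace(-1, 1, 15)


@dataclass(frozen=True)
class ClassifierConfig:
    method: str
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


class BaseLearner:
    """fit/score wrapper giving every method a [0, 1] score interface."""

    def __init__(self, config: ClassifierConfig, estimator, kind: str):
        self.config = config
        self._estimator = estimator
        self._kind = kind  # 'proba' | 'decision' | 'ridge'

    def fresh(self) -> "BaseLearner":
        return BaseLearner(self.config, clone(self._estimator), self._kind)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaseLearner":
        y = np.asarray(y)
        if self._kind == "ridge":
            self._estimator.fit(X, np.where(y == 1, 1.0, -1.0))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                self._estimator.fit(X, y)
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._kind == "proba":
            pos = list(self._estimator.classes_).index(1)
            return self._estimator.predict_proba(X)[:, pos]
        raw = (
            self._estimator.decision_function(X)
            if self._kind == "decision"
            else self._estimator.predict(X)
        )
        return _logistic(raw)

    def score_one(self, x: np.ndarray) -> float:
        return float(self.scores(np.asarray(x)[None, :])[0])


def build_classifier(config: ClassifierConfig) -> BaseLearner:
    """Instantiate one of the five base learners with its fixed settings."""
    seed = config.random_seed
    if config.method == "svm":
        return BaseLearner(
            config, SVC(kernel="linear", class_weight="balanced"), "decision"
        )
    if config.method == "rf":
        return BaseLearner(
            config,
            RandomForestClassifier(
                n_estimators=30,
                criterion="entropy",
                class_weight="balanced_subsample",
                random_state=seed,
            ),
            "proba",
        )
    if config.method == "ridge":
        return BaseLearner(config, Ridge(alpha=1.0), "ridge")
    if config.method == "bnb":
        return BaseLearner(
            config, BernoulliNB(alpha=1.0, binarize=0.0, fit_prior=False), "proba"
        )
    if config.method == "mlp":
        return BaseLearner(
            config,
            MLPClassifier(hidden_layer_sizes=(30,), alpha=0.001, random_state=seed),
            "proba",
        )
    raise ValueError(f"unknown method {config.method!r}")


@dataclass
class LooEvaluation:
    """Out-of-fold LOO scores and summary metrics for one method."""

    scores: pd.Series  # per-sample out-of-fold score
    labels: pd.Series  # per-sample true label, R/NR
    method: str
    flowps_enabled: bool
    roc_auc: float = field(init=False)
    aupr: float = field(init=False)

    def __post_init__(self) -> None:
        y = (self.labels == "R").to_numpy().astype(int)
        self.roc_auc = roc_auc(self.scores.to_numpy(), y)
        self.aupr = aupr(self.scores.to_numpy(), y)


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC AUC (ties counted 1/2); labels are 0/1."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (interpolation-free sum)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return mean, sd


def loo_evaluate(
    features: pd.DataFrame,
    labels: pd.Series,
    config: ClassifierConfig,
    flowps_params: FlowpsParams | None = None,
) -> LooEvaluation:
    """Leave-one-out evaluation of one method on a samples x features table.

    For each sample the learner is trained on the remaining samples —
    optionally through FloWPS trimming — and the left-out sample is scored.
    Features are z-scored with training-fold statistics. With FloWPS enabled
    the feature ranking for top-m selection is the cohort-level oriented AUC
    of the supplied features — the same ranking that defines the core marker
    set. Re-ranking inside each fold is deliberately avoided: dropping a
    sample that is discordant on a gene raises that gene's fold AUC, so a
    per-fold top-m systematically picks the genes on which the held-out
    sample is atypical for its class and scores it on the wrong side. The
    cohort-level ranking shares whatever selection optimism the core-set
    features already carry, identically for the trimmed and untrimmed
    evaluations.
    """
    X = features.to_numpy(dtype=float)
    labels = pd.Series(np.asarray(labels), index=features.index)
    y = (labels == "R").to_numpy().astype(int)
    n = len(labels)
    if min((y == 1).sum(), (y == 0).sum()) < 3:
        raise ValueError("need at least 3 samples per class")

    learner = build_classifier(config)
    if flowps_params is not None:
        cohort_auc = auc_matrix(X.T, labels.to_numpy())
        oriented = np.maximum(cohort_auc, 1 - cohort_auc)
        ranking = np.lexsort((np.arange(len(oriented)), -oriented))
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        X_tr, y_tr = X[mask], y[mask]
        mean, sd = _zscore_fit(X_tr)
        Z_tr = (X_tr - mean) / sd
        z_te = (X[i] - mean) / sd

        if flowps_params is None:
            out[i] = learner.fresh().fit(Z_tr, y_tr).score_one(z_te)
        else:
            out[i] = flowps_predict(
                z_te, Z_tr, y_tr, learner, flowps_params, ranking
            )

    return LooEvaluation(
        scores=pd.Series(out, index=features.index, name="score"),
        labels=labels,
        method=config.method,
        flowps_enabled=flowps_params is not None,
    )


def metrics_vs_balance(
    evaluation: LooEvaluation, B_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Sensitivity/specificity as functions of the balance factor B.

    A sample is called positive iff its score >= tau(B) = B/(1+B); B = 1
    gives the neutral 0.5 threshold, B -> 0 drives sensitivity to 1.
    """
    B_grid = DEFAULT_B_GRID if B_grid is None else np.asarray(B_grid, dtype=float)
    if (B_grid <= 0).any():
        raise ValueError("balance factors must be positive")
    scores = evaluation.scores.to_numpy()
    y = (evaluation.labels == "R").to_numpy()
    rows = []
    for B in B_grid:
        tau = B / (1.0 + B)
        called = scores >= tau
        tp = int((called & y).sum())
        fn = int((~called & y).sum())
        tn = int((~called & ~y).sum())
        fp = int((called & ~y).sum())
        rows.append(
            {
                "B": B,
                "threshold": tau,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def evaluate_all_methods(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    flowps_params: FlowpsParams | None = None,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """ROC AUC / AUPR for every method with and without FloWPS.

    Returns a table shaped like the study's summary: one row per method,
    columns for each metric without/with trimming.
    """
    if flowps_params is None:
        flowps_params = FlowpsParams.default_grid(
            n_train=len(features) - 1, n_features=features.shape[1]
        )
    rows = []
    for method in methods:
        config = ClassifierConfig(method=method, random_seed=seed)
        plain = loo_evaluate(features, labels, config)
        trimmed = loo_evaluate(features, labels, config, flowps_params)
        rows.append(
            {
                "method": method,
                "roc_auc": plain.roc_auc,
                "roc_auc_flowps": trimmed.roc_auc,
                "aupr": plain.aupr,
                "aupr_flowps": trimmed.aupr,
            }
        )
    return pd.DataFrame(rows).set_index("method")
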
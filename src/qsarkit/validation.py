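"""Classification scoring, cross-validation, Y-randomization and
applicability domains (leverage- and distance-based, plus the consensus
conjunction rule).

Scores follow the standard binary-classification definitions with an
explicit positive class (BBB+ in the barrier-permeability study):
Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/n and balanced accuracy
BA = (Sn+Sp)/2. Cross-validation folds are stratified so unbalanced
class ratios survive the partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .errors import SingularMatrixError
from .modeling import pairwise_distances


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive: str = "BBB+"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ScoreReport:
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    counts: ConfusionCounts | None = None

    def __post_init__(self):
        sn, sp, ba = self.sensitivity, self.specificity, self.balanced_accuracy
        if not (math.isnan(sn) or math.isnan(sp)):
            if abs(ba - (sn + sp) / 2) > 1e-12:
                raise ValueError("balanced accuracy must equal (Sn+Sp)/2")


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        positive=str(positive),
    )


def classification_scores(y_true, y_pred, positive="BBB+") -> ScoreReport:
    """Sensitivity/specificity/accuracy/balanced accuracy; a class
    absent from ``y_true`` leaves its rate NaN with a warning."""
    c = confusion_counts(y_true, y_pred, positive)
    if c.tp + c.fn == 0:
        warnings.warn("positive class absent: sensitivity undefined")
        sn = math.nan
    else:
        sn = c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        warnings.warn("negative class absent: specificity undefined")
        sp = math.nan
    else:
        sp = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.n if c.n else math.nan
    ba = (sn + sp) / 2
    return ScoreReport(sn, sp, acc, ba, c)


@dataclass
class CVResult:
    fold_reports: list[ScoreReport]
    pooled_accuracy: float
    pooled_report: ScoreReport
    predictions: np.ndarray
    fold_of: np.ndarray


def cross_validate(model, X, y, folds: int = 5, seed: int | None = None,
                   positive="BBB+") -> CVResult:
    """Seeded stratified k-fold CV: each sample predicted exactly once
    by a model trained without it; pooled accuracy over all out-of-fold
    predictions."""
    X = np.asarray(X)
    y = np.asarray(y)
    if folds < 2 or len(y) < folds:
        raise ValueError("need folds >= 2 and n >= folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty(len(y), dtype=y.dtype)
    fold_of = np.empty(len(y), dtype=int)
    reports = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        if len(np.unique(y[test])) < 2:
            warnings.warn(f"fold {fold} lacks one class")
        est = clone(model).fit(X[train], y[train])
        p = est.predict(X[test])
        preds[test] = p
        fold_of[test] = fold
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(classification_scores(y[test], p, positive))
    pooled = classification_scores(y, preds, positive)
    return CVResult(reports, float(np.mean(preds == y)), pooled, preds, fold_of)


def y_randomization(model, X, y, n_iter: int = 20, seed: int | None = None,
                    folds: int = 5, positive="BBB+") -> dict:
    """Refit and score the model on label permutations; a real model
    should beat every permuted score (which collapse to the
    majority-class rate)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    scores = []
    for i in range(n_iter):
        perm = rng.permutation(len(y))
        result = cross_validate(model, X, y[perm], folds=folds,
                                seed=int(rng.integers(2**31)), positive=positive)
        scores.append(result.pooled_accuracy)
    return {
        "scores": scores,
        "mean": float(np.mean(scores)),
        "sd": float(np.std(scores, ddof=1)) if n_iter > 1 else 0.0,
        "n_iter": n_iter,
    }


# ---------------------------------------------------------------------------
# Applicability domains
# ---------------------------------------------------------------------------


class LeverageAD:
    """Hat-matrix (leverage) applicability domain.

    h(x) = x~ (X~'X~)^-1 x~' with intercept-augmented X~; a query is
    inside iff h <= h* = 3(p+1)/n (the conventional Williams-plot cut).
    Fitted on the training descriptor matrix only.
    """

    kind = "leverage"

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        Xa = np.column_stack([np.ones(n), X])
        xtx = Xa.T @ Xa
        if np.linalg.cond(xtx) > 1e10:
            raise SingularMatrixError(
                "X'X is (near-)singular; run variable reduction first"
            )
        self.xtx_inv_ = np.linalg.inv(xtx)
        self.n_train_ = n
        self.p_ = p
        self.threshold_ = (
            self.threshold if self.threshold is not None else 3.0 * (p + 1) / n
        )
        self.training_leverages_ = self.values(X)
        return self

    def values(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        Xa = np.column_stack([np.ones(X.shape[0]), X])
        return np.einsum("ij,jk,ik->i", Xa, self.xtx_inv_, Xa)

    def contains(self, X) -> np.ndarray:
        return self.values(X) <= self.threshold_


class DistanceAD:
    """Distance-to-training applicability domain.

    The AD statistic is the mean distance to the ``k`` nearest training
    molecules; the threshold is a percentile (default 95th) of the
    leave-self-out training statistics.
    """

    kind = "distance"

    def __init__(self, metric: str = "euclidean", k: int = 5,
                 percentile: float = 95.0):
        self.metric = metric
        self.k = k
        self.percentile = percentile

    def fit(self, X):
        if self.metric == "jaccard_tanimoto":
            X = np.asarray(X, dtype=bool)
        else:
            X = np.asarray(X, dtype=float)
        self.X_ = X
        D = pairwise_distances(X, X, self.metric)
        np.fill_diagonal(D, np.inf)
        D.sort(axis=1)
        k = min(self.k, X.shape[0] - 1)
        self.training_values_ = D[:, :k].mean(axis=1)
        self.threshold_ = float(np.percentile(self.training_values_, self.percentile))
        return self

    def values(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        D = pairwise_distances(X, self.X_, self.metric)
        D.sort(axis=1)
        k = min(self.k, self.X_.shape[0])
        return D[:, :k].mean(axis=1)

    def contains(self, X) -> np.ndarray:
        return self.values(X) <= self.threshold_


def leverage_fit(X_train) -> LeverageAD:
    return LeverageAD().fit(X_train)


def leverage_value(ad: LeverageAD, x):
    h = float(ad.values(x)[0])
    return h, bool(h <= ad.threshold_)


def distance_ad_fit(X_train, metric: str = "euclidean", k_ad: int = 5,
                    percentile: float = 95.0) -> DistanceAD:
    return DistanceAD(metric=metric, k=k_ad, percentile=percentile).fit(X_train)


def distance_ad_value(ad: DistanceAD, x):
    d = float(ad.values(x)[0])
    return d, bool(d <= ad.threshold_)


def consensus_ad(member_results) -> bool:
    """A molecule is inside the consensus AD only if it is inside the
    AD of every member model (logical conjunction)."""
    results = list(member_results)
    if not results:
        raise ValueError("consensus AD needs at least one member result")
    return all(bool(r) for r in results)
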
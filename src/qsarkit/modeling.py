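"""Dataset splitting, feature pretreatment, variable reduction, KNN and
consensus classifiers, and genetic-algorithm feature selection.

The classifiers follow the scikit-learn estimator contract (``fit`` /
``predict`` / ``get_params``; fitted attributes carry a trailing
underscore) so they compose with sklearn pipelines and model selection.
Distances are brute-force: Jaccard–Tanimoto for bit fingerprints,
Euclidean for (standardized) real-valued descriptors.

Determinism rules: at a distance tie on the k-th neighbour rank, the
lowest training index wins; a 50:50 vote with even k falls back to the
class of the single nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .errors import ConfigurationError, ZeroVarianceError

METRICS = ("jaccard_tanimoto", "euclidean")


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass
class Split:
    train_ids: list[int]
    test_ids: list[int]
    method: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def split_dataset(
    data,
    method: str = "random",
    test_fraction: float = 0.2,
    every: int = 5,
    column: str | None = None,
    seed: int | None = None,
) -> Split:
    """Partition row ids into training and test sets.

    ``data`` is an integer row count, a DataFrame, or a MoleculeTable.
    Methods: ``random`` (seeded shuffle, ``test_fraction`` held out),
    ``venetian`` (every ``every``-th row to the test set), and
    ``by_variable`` (rows with a non-empty value in ``column`` train,
    the rest test — e.g. a database-identifier column).
    """
    frame = getattr(data, "data", data)
    n = frame if isinstance(frame, int) else len(frame)
    ids = list(range(n))
    if method == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_test = int(round(n * test_fraction))
        test = sorted(int(i) for i in perm[:n_test])
        train = sorted(int(i) for i in perm[n_test:])
    elif method == "venetian":
        test = [i for i in ids if i % every == every - 1]
        train = [i for i in ids if i % every != every - 1]
    elif method == "by_variable":
        if isinstance(frame, int) or column not in frame.columns:
            raise ConfigurationError(f"by_variable needs a data column ({column!r})")
        values = frame[column]
        train = [i for i in ids if not (pd.isna(values.iloc[i]) or values.iloc[i] == "")]
        test = [i for i in ids if i not in set(train)]
    else:
        raise ConfigurationError(f"unknown split method: {method!r}")
    if not train or not test:
        raise ValueError("split produced an empty training or test set")
    return Split(train, test, method,
                 {"test_fraction": test_fraction, "every": every, "column": column},
                 seed)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardization:
    """Per-feature mean/sd learned on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) / self.sd


def standardize_fit(X, training_ids=None) -> Standardization:
    X = np.asarray(X, dtype=float)
    if training_ids is not None:
        X = X[np.asarray(training_ids)]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0])
        raise ZeroVarianceError(
            f"constant feature column(s) {bad}; run variable reduction first"
        )
    return Standardization(mean, sd)


def standardize_apply(std: Standardization, X) -> np.ndarray:
    return std.apply(X)


# ---------------------------------------------------------------------------
# Variable reduction
# ---------------------------------------------------------------------------


def variable_reduction(
    matrix: pd.DataFrame,
    drop_constant: bool = True,
    quasi_constant_sd_threshold: float | None = None,
    pairwise_correlation_threshold: float | None = None,
    missing_policy: str | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop constant / quasi-constant / highly inter-correlated columns.

    Missing values are handled first per policy (``drop_molecule`` or
    ``drop_feature``); of a pair with |r| above the threshold the
    later column is dropped. Returns the reduced matrix and a log.
    """
    df = matrix.copy()
    log = []
    if df.isna().any().any():
        if missing_policy == "drop_molecule":
            bad = df.index[df.isna().any(axis=1)]
            log.append({"step": "missing_drop_molecule", "rows": list(bad)})
            df = df.drop(index=bad)
        elif missing_policy == "drop_feature":
            bad = [c for c in df.columns if df[c].isna().any()]
            log.append({"step": "missing_drop_feature", "columns": bad})
            df = df.drop(columns=bad)
        elif missing_policy is not None:
            raise ConfigurationError(f"unknown missing policy: {missing_policy!r}")

    if drop_constant:
        bad = [c for c in df.columns if df[c].nunique(dropna=False) <= 1]
        if bad:
            log.append({"step": "constant", "columns": bad})
            df = df.drop(columns=bad)
    if quasi_constant_sd_threshold is not None:
        sds = df.std(ddof=0)
        bad = [c for c in df.columns if sds[c] < quasi_constant_sd_threshold]
        if bad:
            log.append({"step": "quasi_constant", "columns": bad})
            df = df.drop(columns=bad)
    if pairwise_correlation_threshold is not None and df.shape[1] > 1:
        corr = df.corr().abs()
        cols = list(df.columns)
        dropped = []
        for j, cj in enumerate(cols):
            if cj in dropped:
                continue
            for ci in cols[:j]:
                if ci in dropped:
                    continue
                if corr.loc[ci, cj] > pairwise_correlation_threshold:
                    dropped.append(cj)
                    break
        if dropped:
            log.append({"step": "correlated", "columns": dropped})
            df = df.drop(columns=dropped)
    if df.shape[1] == 0:
        raise ValueError("variable reduction removed every feature")
    return df, log


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------


def pairwise_distances(A, B, metric: str) -> np.ndarray:
    if metric == "jaccard_tanimoto":
        return cdist(np.asarray(A, dtype=bool), np.asarray(B, dtype=bool), "jaccard")
    if metric == "euclidean":
        return cdist(np.asarray(A, dtype=float), np.asarray(B, dtype=float))
    raise ConfigurationError(f"unknown metric: {metric!r}")


class KNNClassifier(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour classifier with Jaccard–Tanimoto or
    Euclidean distance and optional training-set standardization.

    Parameters
    ----------
    k : neighbour count (>= 1, <= training size).
    metric : "jaccard_tanimoto" for bit features, "euclidean" for
        real-valued features.
    standardize : learn per-feature mean/sd on the training rows and
        apply them to queries. Required for unscaled real features
        unless ``allow_unstandardized`` is set.
    """

    def __init__(self, k: int = 5, metric: str = "euclidean",
                 standardize: bool = False, allow_unstandardized: bool = False):
        self.k = k
        self.metric = metric
        self.standardize = standardize
        self.allow_unstandardized = allow_unstandardized

    def fit(self, X, y):
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric: {self.metric!r}")
        X = np.asarray(X)
        y = np.asarray(y)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        self.scaler_ = None
        if self.metric == "euclidean":
            if self.standardize:
                self.scaler_ = standardize_fit(X)
                X = self.scaler_.apply(X)
            elif not self.allow_unstandardized:
                raise ConfigurationError(
                    "euclidean KNN on unstandardized features; set "
                    "standardize=True (or allow_unstandardized=True to force)"
                )
            X = np.asarray(X, dtype=float)
        else:
            X = np.asarray(X, dtype=bool)
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def _prepare(self, X):
        X = np.asarray(X)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if self.scaler_ is not None:
            X = self.scaler_.apply(X)
        return X

    def kneighbors(self, X, k: int | None = None):
        """Indices, distances and classes of the k nearest training
        molecules for each query row; equidistant candidates at the
        cut rank are resolved toward the lowest training index."""
        k = self.k if k is None else k
        X = self._prepare(X)
        D = pairwise_distances(X, self.X_, self.metric)
        n_train = self.X_.shape[0]
        order = np.lexsort((np.tile(np.arange(n_train), (D.shape[0], 1)), D), axis=1)
        idx = order[:, :k]
        dist = np.take_along_axis(D, idx, axis=1)
        return idx, dist, self.y_[idx]

    @staticmethod
    def _vote(labels):
        out = []
        for row_labels in labels:
            values, counts = np.unique(row_labels, return_counts=True)
            best = counts.max()
            winners = values[counts == best]
            if len(winners) == 1:
                out.append(winners[0])
            else:
                out.append(row_labels[0])  # tie: nearest neighbour decides
        return np.asarray(out)

    def predict(self, X):
        idx, dist, labels = self.kneighbors(X)
        return self._vote(labels)

    def neighbor_detail(self, X):
        """Per-query neighbour report (ids, distances, classes) for
        interpretability."""
        idx, dist, labels = self.kneighbors(X)
        return [
            {"ids": list(map(int, idx[i])),
             "distances": list(map(float, dist[i])),
             "classes": list(labels[i])}
            for i in range(idx.shape[0])
        ]

    def training_predictions(self, include_self: bool = True):
        """Predict every training row. With ``include_self`` the row is
        its own nearest neighbour (distance 0), the common convention
        for reported training scores; without it, the honest
        leave-self-out variant."""
        D = pairwise_distances(self.X_, self.X_, self.metric)
        if not include_self:
            np.fill_diagonal(D, np.inf)
        n = self.X_.shape[0]
        order = np.lexsort((np.tile(np.arange(n), (n, 1)), D), axis=1)
        idx = order[:, : self.k]
        return self._vote(self.y_[idx])


def knn_fit(X, y, k: int = 5, metric: str = "euclidean",
            standardize: bool = False) -> KNNClassifier:
    return KNNClassifier(k=k, metric=metric, standardize=standardize).fit(X, y)


def knn_predict(model: KNNClassifier, X):
    """(labels, neighbour detail) for a fitted KNN model."""
    return model.predict(X), model.neighbor_detail(X)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def majority_vote(votes, tie_rule: str | None = None):
    """Majority label of one vote sequence; even ties raise unless a
    tie rule ("first_member") is configured."""
    votes = list(votes)
    values, counts = np.unique(votes, return_counts=True)
    best = counts.max()
    winners = values[counts == best]
    if len(winners) == 1:
        return winners[0]
    if tie_rule == "first_member":
        return votes[0]
    raise ValueError("tied consensus vote and no tie rule configured")


class ConsensusClassifier(BaseEstimator, ClassifierMixin):
    """Majority vote over member classifiers sharing one feature space.

    For members living in different feature spaces (fingerprints vs
    descriptors) aggregate their prediction columns with
    :func:`majority_vote` / :meth:`predict_from_votes` instead.
    """

    def __init__(self, members=None, tie_rule: str | None = None):
        self.members = members
        self.tie_rule = tie_rule

    def fit(self, X, y):
        if not self.members or len(self.members) < 2:
            raise ValueError("consensus needs at least 2 members")
        self.members_ = [clone(m).fit(X, y) for m in self.members]
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        votes = np.column_stack([m.predict(X) for m in self.members_])
        return self.predict_from_votes(votes)

    def predict_from_votes(self, votes):
        votes = np.asarray(votes)
        return np.asarray(
            [majority_vote(row, self.tie_rule) for row in votes]
        )


def consensus_predict(consensus: ConsensusClassifier, X):
    return consensus.predict(X)


# ---------------------------------------------------------------------------
# Genetic-algorithm feature selection
# ---------------------------------------------------------------------------


@dataclass
class GAConfig:
    """Feature-selection GA settings. Defaults follow the package's
    standard configuration; the subset-size cap mirrors the descriptor
    cap used when the BBB model was selected (at most 10 features)."""

    max_features: int = 10
    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/n_features
    tournament_size: int = 3
    elite: int = 1
    seed: int | None = None

    def validate(self, n_features: int):
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.max_features > n_features:
            raise ValueError("max_features exceeds available features")
        for rate in (self.crossover_rate, self.mutation_rate or 0.0):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")


def _repair(mask: np.ndarray, max_features: int, rng) -> np.ndarray:
    on = np.where(mask)[0]
    if len(on) > max_features:
        drop = rng.choice(on, size=len(on) - max_features, replace=False)
        mask = mask.copy()
        mask[drop] = False
    elif len(on) == 0:
        mask = mask.copy()
        mask[rng.integers(len(mask))] = True
    return mask


def ga_select(X, y, config: GAConfig, evaluator=None):
    """Evolve feature subsets by tournament selection, uniform
    crossover and per-gene mutation with elitism.

    ``evaluator(feature_indices) -> score`` defaults to 5-fold CV
    balanced accuracy of a standardized Euclidean KNN. Returns the best
    subsets (ranked) and the per-generation best-fitness history
    (non-decreasing under elitism).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    config.validate(n_features)
    rng = np.random.default_rng(config.seed)
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_features

    if evaluator is None:
        from .validation import cross_validate

        def evaluator(subset):
            model = KNNClassifier(k=5, metric="euclidean", standardize=True)
            result = cross_validate(model, X[:, list(subset)], y, folds=5,
                                    seed=config.seed or 0)
            bas = [r.balanced_accuracy for r in result.fold_reports]
            return float(np.nanmean(bas))

    cache: dict[tuple, float] = {}

    def fitness(mask):
        key = tuple(np.where(mask)[0])
        if key not in cache:
            cache[key] = evaluator(key)
        return cache[key]

    pop = []
    for _ in range(config.population_size):
        size = rng.integers(1, config.max_features + 1)
        mask = np.zeros(n_features, dtype=bool)
        mask[rng.choice(n_features, size=size, replace=False)] = True
        pop.append(mask)

    history = []
    scores = np.array([fitness(m) for m in pop])
    for _ in range(config.generations):
        order = np.argsort(-scores, kind="stable")
        elite = [pop[i].copy() for i in order[: config.elite]]
        children = list(elite)
        while len(children) < config.population_size:
            def pick():
                contenders = rng.integers(0, config.population_size,
                                          size=config.tournament_size)
                return pop[max(contenders, key=lambda i: scores[i])]

            a, b = pick().copy(), pick().copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(n_features) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                flip = rng.random(n_features) < mut
                child[flip] = ~child[flip]
                children.append(_repair(child, config.max_features, rng))
        pop = children[: config.population_size]
        scores = np.array([fitness(m) for m in pop])
        history.append(float(scores.max()))

    order = np.argsort(-scores, kind="stable")
    best = [tuple(np.where(pop[i])[0]) for i in order]
    # deduplicate preserving rank
    seen, ranked = set(), []
    for subset in best:
        if subset not in seen:
            seen.add(subset)
            ranked.append(subset)
    return ranked, history
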
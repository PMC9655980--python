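"""Splits, pretreatment, variable reduction, KNN/consensus and GA
feature selection."""

import numpy as np
import pandas as pd
import pytest

from qsarkit import fixtures
from qsarkit.errors import ConfigurationError, ZeroVarianceError
from qsarkit.modeling import (
    ConsensusClassifier,
    GAConfig,
    KNNClassifier,
    Standardization,
    ga_select,
    majority_vote,
    split_dataset,
    standardize_apply,
    standardize_fit,
    variable_reduction,
)


class TestSplits:
    def test_venetian_8_2(self):
        split = split_dataset(10, "venetian", every=5)
        assert len(split.train_ids) == 8 and len(split.test_ids) == 2

    def test_random_seed_reproducible(self):
        a = split_dataset(50, "random", seed=7)
        b = split_dataset(50, "random", seed=7)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_by_variable_nonempty_to_training(self):
        frame = pd.DataFrame({"cid": ["1", "", "3", "", "5"]})
        split = split_dataset(frame, "by_variable", column="cid")
        assert split.train_ids == [0, 2, 4] and split.test_ids == [1, 3]

    @pytest.mark.parametrize("method,kwargs", [
        ("random", {"seed": 0}), ("venetian", {"every": 3}),
    ])
    def test_partition_property(self, method, kwargs):
        split = split_dataset(23, method, **kwargs)
        assert sorted(split.train_ids + split.test_ids) == list(range(23))

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            split_dataset(10, "bogus")


class TestStandardization:
    def test_simple_column(self):
        std = standardize_fit(np.array([[1.0], [2.0], [3.0]]))
        out = standardize_apply(std, np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-np.sqrt(1.5), 0, np.sqrt(1.5)])

    def test_test_value_at_training_mean_maps_to_zero(self):
        std = standardize_fit(np.array([[1.0], [3.0]]))
        assert standardize_apply(std, np.array([[2.0]]))[0, 0] == 0.0

    def test_constant_column_raises(self):
        with pytest.raises(ZeroVarianceError):
            standardize_fit(np.array([[1.0], [1.0], [1.0]]))

    def test_fit_apply_roundtrip_moments(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(40, 4))
        out = standardize_apply(standardize_fit(X), X)
        assert np.all(np.abs(out.mean(axis=0)) < 1e-12)
        assert np.all(np.abs(out.std(axis=0) - 1) < 1e-12)


class TestVariableReduction:
    def test_constant_dropped(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        out, log = variable_reduction(df)
        assert list(out.columns) == ["b"]

    def test_duplicated_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out, _ = variable_reduction(df, pairwise_correlation_threshold=0.99)
        assert list(out.columns) == ["a"]

    def test_missing_drop_molecule_keeps_features(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 4.0]})
        out, _ = variable_reduction(df, missing_policy="drop_molecule")
        assert list(out.columns) == ["a", "b"] and len(out) == 2

    def test_all_removed_is_error(self):
        df = pd.DataFrame({"a": [1.0, 1.0]})
        with pytest.raises(ValueError):
            variable_reduction(df)


class TestKNN:
    def test_one_dimensional_example(self):
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array(["+", "+", "-"])
        m = KNNClassifier(k=1, metric="euclidean", allow_unstandardized=True).fit(X, y)
        assert m.predict([[0.4]])[0] == "+"

    def test_k_equals_n_global_majority(self):
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array(["+", "+", "-"])
        m = KNNClassifier(k=3, metric="euclidean", allow_unstandardized=True).fit(X, y)
        assert m.predict([[100.0]])[0] == "+"

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            KNNClassifier(k=0).fit(np.zeros((3, 1)), np.array(["a", "b", "a"]))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            KNNClassifier(k=5, metric="euclidean", allow_unstandardized=True).fit(
                np.zeros((3, 1)), np.array(["a", "b", "a"])
            )

    def test_training_point_returns_own_class(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = np.array(["a", "b"] * 10)
        m = KNNClassifier(k=1, metric="euclidean", standardize=True).fit(X, y)
        assert list(m.predict(X)) == list(y)

    def test_distance_tie_resolved_to_lowest_index(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [5.0, 5.0]])
        y = np.array(["a", "b", "b"])
        m = KNNClassifier(k=1, metric="euclidean", allow_unstandardized=True).fit(X, y)
        # query equidistant from rows 0 and 1 -> row 0 wins
        assert m.predict([[0.0, 0.0]])[0] == "a"

    def test_even_k_vote_tie_falls_to_nearest(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["a", "b", "b", "a"])
        m = KNNClassifier(k=2, metric="euclidean", allow_unstandardized=True).fit(X, y)
        assert m.predict([[0.9]])[0] == "b"

    def test_unstandardized_euclidean_refused(self):
        with pytest.raises(ConfigurationError):
            KNNClassifier(k=1, metric="euclidean").fit(
                np.zeros((4, 2)), np.array(["a", "b", "a", "b"])
            )

    def test_jaccard_on_bits(self):
        X = np.array([[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 1, 0]], dtype=bool)
        y = np.array(["p", "n", "p"])
        m = KNNClassifier(k=1, metric="jaccard_tanimoto").fit(X, y)
        assert m.predict(np.array([[1, 1, 0, 1]], dtype=bool))[0] == "p"

    def test_neighbor_detail_exposed(self):
        X = np.array([[0.0], [2.0]])
        y = np.array(["a", "b"])
        m = KNNClassifier(k=2, metric="euclidean", allow_unstandardized=True).fit(X, y)
        detail = m.neighbor_detail([[0.1]])[0]
        assert detail["ids"] == [0, 1]
        assert detail["classes"] == ["a", "b"]
        assert detail["distances"][0] == pytest.approx(0.1)

    def test_training_predictions_conventions(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array(["a", "b", "c", "d"])
        m = KNNClassifier(k=1, metric="euclidean", allow_unstandardized=True).fit(X, y)
        assert list(m.training_predictions(include_self=True)) == list(y)
        assert list(m.training_predictions(include_self=False)) == ["b", "a", "d", "c"]


class TestConsensus:
    def test_majority_votes(self):
        assert majority_vote(["+", "+", "-"]) == "+"
        assert majority_vote(["-", "-", "-"]) == "-"

    def test_even_tie_errors_without_rule(self):
        with pytest.raises(ValueError):
            majority_vote(["+", "-"])
        assert majority_vote(["+", "-"], tie_rule="first_member") == "+"

    def test_identical_members_equal_single_member(self):
        X, y = fixtures.synthetic_classification(n_per_class=20, seed=0)
        Xn = X.to_numpy()
        member = KNNClassifier(k=3, metric="euclidean", standardize=True)
        consensus = ConsensusClassifier([member, member, member]).fit(Xn, y)
        single = KNNClassifier(k=3, metric="euclidean", standardize=True).fit(Xn, y)
        assert np.array_equal(consensus.predict(Xn), single.predict(Xn))

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            ConsensusClassifier([KNNClassifier()]).fit(
                np.zeros((4, 2)), np.array(["a", "b", "a", "b"])
            )


class TestGA:
    def test_elitism_history_non_decreasing_and_seed_reproducible(self):
        X, y = fixtures.synthetic_classification(
            n_per_class=30, n_noise=8, seed=4
        )
        cfg = GAConfig(max_features=4, population_size=10, generations=6, seed=11)
        best1, hist1 = ga_select(X.to_numpy(), y, cfg)
        best2, hist2 = ga_select(X.to_numpy(), y, cfg)
        assert hist1 == hist2 and best1[0] == best2[0]
        assert all(b >= a for a, b in zip(hist1, hist1[1:]))

    def test_subset_size_capped(self):
        X, y = fixtures.synthetic_classification(n_per_class=20, n_noise=8, seed=1)
        cfg = GAConfig(max_features=3, population_size=8, generations=4, seed=2)
        best, _ = ga_select(X.to_numpy(), y, cfg)
        assert all(len(s) <= 3 for s in best)

    def test_max_features_validated(self):
        X, y = fixtures.synthetic_classification(n_per_class=20, n_noise=3, seed=1)
        cfg = GAConfig(max_features=99, population_size=8, generations=2)
        with pytest.raises(ValueError):
            ga_select(X.to_numpy(), y, cfg)
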
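"""RFDDT forest: training behavior, voting, metrics, benchmark harness."""

import math
import warnings

import numpy as np
import pytest

from ecgkit import (ConfusionMatrix, Dataset, RfddtClassifier, RfddtParams,
                    benchmark, confusion, fit_rfddt, metrics, predict)
from ecgkit.errors import (EmptyDatasetError, ShapeError, StratificationError)
from ecgkit.forest import bootstrap_indices, default_classifier_set


def two_clusters(n_per=100, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-sep, 1.0, (n_per, 2)),
                   rng.normal(sep, 1.0, (n_per, 2))])
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


def xor_clusters(n=400, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[2, 2], [-2, -2], [2, -2], [-2, 2]], dtype=float)
    X = centers.repeat(n // 4, axis=0) + rng.normal(0, 0.5, (n, 2))
    y = np.array(["p"] * (n // 2) + ["q"] * (n // 2))
    return X, y


class TestFit:
    def test_separated_clusters_perfect_heldout(self):
        X, y = two_clusters(seed=0)
        Xt, yt = two_clusters(n_per=50, seed=1)
        model = fit_rfddt(Dataset(X, y), RfddtParams(n_trees=100), seed=0)
        assert np.mean(predict(model, Xt) == yt) == 1.0

    def test_xor_needs_depth(self):
        X, y = xor_clusters(seed=0)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        tr, te = idx[:300], idx[300:]
        model = fit_rfddt(Dataset(X[tr], y[tr]), RfddtParams(n_trees=100), seed=0)
        assert np.mean(predict(model, X[te]) == y[te]) >= 0.95

    def test_single_class_constant_predictor(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        y = np.array(["only"] * 20)
        with pytest.warns(UserWarning):
            model = fit_rfddt(Dataset(X, y), RfddtParams(n_trees=5), seed=0)
        assert np.all(predict(model, X) == "only")

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyDatasetError):
            Dataset(np.zeros((0, 2)), np.array([]))

    def test_deterministic_for_fixed_seed(self):
        X, y = two_clusters(seed=3)
        m1 = fit_rfddt(Dataset(X, y), RfddtParams(n_trees=20), seed=9)
        m2 = fit_rfddt(Dataset(X, y), RfddtParams(n_trees=20), seed=9)
        Xt = np.random.default_rng(1).normal(0, 3, (100, 2))
        assert np.array_equal(predict(m1, Xt), predict(m2, Xt))
        for t1, t2 in zip(m1.trees, m2.trees):
            assert np.array_equal(t1.feature, t2.feature)
            assert np.allclose(t1.threshold, t2.threshold, equal_nan=True)

    def test_deep_trees_memorize_training_points(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 4))
        y = np.array(["a", "b"] * 50)
        model = fit_rfddt(Dataset(X, y), RfddtParams(n_trees=50), seed=0)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_bootstrap_unique_fraction(self):
        fracs = [np.unique(bootstrap_indices(1000, s)).size / 1000
                 for s in range(200)]
        assert abs(np.mean(fracs) - (1 - math.exp(-1))) <= 0.02


class TestPredict:
    def test_single_tree_forest_returns_leaf_class(self):
        X, y = two_clusters(n_per=20, seed=0)
        model = fit_rfddt(Dataset(X, y), RfddtParams(n_trees=1), seed=0)
        assert set(predict(model, X)) <= set(y)

    def test_feature_count_mismatch_rejected(self):
        X, y = two_clusters(n_per=10)
        model = fit_rfddt(Dataset(X, y), RfddtParams(n_trees=2), seed=0)
        with pytest.raises(ShapeError):
            predict(model, np.zeros((3, 5)))

    def test_tie_breaks_lexicographically(self):
        # one pure-leaf tree per class by training three 1-tree forests is
        # hard to force; instead check the vote argmax convention directly
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["c", "b", "a"])
        model = fit_rfddt(Dataset(X, y), RfddtParams(n_trees=3), seed=1)
        votes_classes = model.classes
        assert list(votes_classes) == sorted(votes_classes)


class TestMetrics:
    def test_exact_counts_example(self):
        m = metrics(ConfusionMatrix(tp=90, fn=10, tn=80, fp=20))
        assert m.as_tuple() == (85.0, 90.0, 80.0)

    def test_symmetric_counts(self):
        m = metrics(ConfusionMatrix(tp=25, fp=25, fn=25, tn=25))
        assert m.as_tuple() == (50.0, 50.0, 50.0)

    def test_undefined_sensitivity_is_nan(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))
        assert math.isnan(m.sensitivity)

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyDatasetError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_perfect_prediction_no_errors(self):
        y = np.array(["a", "b", "a"])
        cm = confusion(y, y, "a")
        assert cm.fp == cm.fn == 0

    def test_all_positives_missed(self):
        yt = np.array(["pos"] * 7)
        yp = np.array(["neg"] * 7)
        cm = confusion(yt, yp, "pos")
        assert cm.tp == 0 and cm.fn == 7

    def test_counts_match_tally_oracle(self):
        rng = np.random.default_rng(0)
        yt = rng.choice(["x", "y"], 1000)
        yp = rng.choice(["x", "y"], 1000)
        cm = confusion(yt, yp, "x")
        tp = fp = fn = tn = 0
        for a, b in zip(yt, yp):
            if a == "x" and b == "x":
                tp += 1
            elif a != "x" and b == "x":
                fp += 1
            elif a == "x":
                fn += 1
            else:
                tn += 1
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        assert cm.n == 1000

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            confusion(np.array(["a"]), np.array(["a", "b"]), "a")


class TestBenchmark:
    def test_separable_three_class_all_high(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 0.3, (30, 2)) for c in (-5.0, 0.0, 5.0)])
        y = np.repeat(["a", "b", "c"], 30)
        table = benchmark(default_classifier_set(seed=0), Dataset(X, y),
                          cv_folds=3, seed=0)
        assert set(table.index) >= {"RFDDT", "SVM", "KNN"}
        assert (table["accuracy"] >= 99.0).all()

    def test_single_classifier_report_shape(self):
        X, y = two_clusters(n_per=20)
        table = benchmark({"RFDDT": RfddtClassifier(seed=0)}, Dataset(X, y),
                          cv_folds=2, seed=0)
        assert table.shape == (1, 3)

    def test_permutation_null_accuracy_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((500, 8))
        y = rng.permutation(np.array(["a", "b"] * 250))
        table = benchmark({"RFDDT": RfddtClassifier(seed=0)}, Dataset(X, y),
                          cv_folds=5, seed=0)
        assert 45.0 <= table.loc["RFDDT", "accuracy"] <= 55.0

    def test_too_many_folds_rejected(self):
        X, y = two_clusters(n_per=3)
        with pytest.raises(StratificationError):
            benchmark({"RFDDT": RfddtClassifier()}, Dataset(X, y), cv_folds=4)
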
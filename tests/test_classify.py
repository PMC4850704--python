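"""LDA estimator, performance indices, and the iterated balanced evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from hdemg.classify import (
    ShrinkageLDA,
    evaluate_iterated,
    performance_indices,
    train_lda,
)
from hdemg.errors import BalanceError, ParameterError


def _two_gaussians(rng, n=50, d0=0.0, d1=10.0, dim=1):
    X = np.vstack([
        rng.normal(d0, 1.0, (n, dim)),
        rng.normal(d1, 1.0, (n, dim)),
    ])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestShrinkageLDA:
    def test_two_class_boundary_near_midpoint(self):
        rng = np.random.default_rng(0)
        X, y = _two_gaussians(rng)
        model = train_lda(X, y)
        # decision threshold: x where the two discriminant scores are equal
        (a0, a1), (b0, b1) = model._coef[:, 0], model._intercept
        threshold = (b0 - b1) / (a1 - a0)
        assert 4.0 <= threshold <= 6.0
        Xt, yt = _two_gaussians(rng, n=500)
        assert (model.predict(Xt) == yt).mean() > 0.99

    def test_duplicate_columns_train_with_ridge(self):
        rng = np.random.default_rng(1)
        X, y = _two_gaussians(rng, dim=1)
        X = np.hstack([X, X])  # rank-deficient pooled covariance
        model = ShrinkageLDA(reg=1e-6).fit(X, y)
        assert (model.predict(X) == y).mean() > 0.99

    def test_separable_training_predictions_perfect(self):
        rng = np.random.default_rng(2)
        X, y = _two_gaussians(rng, d1=30.0, dim=3)
        model = train_lda(X, y)
        assert (model.predict(X) == y).all()

    def test_class_mean_predicts_that_class(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (60, 4)) + np.repeat(np.eye(4)[:3] * 5, 20, axis=0)
        y = np.repeat([0, 1, 2], 20)
        model = train_lda(X, y)
        means = np.vstack([X[y == c].mean(axis=0) for c in range(3)])
        assert (model.predict(means) == [0, 1, 2]).all()

    def test_tie_breaks_toward_first_class_label(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array(["b", "b", "a", "a"])
        model = train_lda(X, y)
        # the midpoint is equidistant: scores tie, argmax takes 'a' (sorted first)
        assert model.predict([[0.0]])[0] == "a"

    def test_scores_match_brute_force_discriminant(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (90, 5)) + np.repeat(rng.normal(0, 3, (3, 5)), 30, axis=0)
        y = np.repeat([0, 1, 2], 30)
        model = train_lda(X, y, reg=1e-8)
        prec = np.linalg.inv(model.covariance_)
        Xq = rng.normal(0, 2, (100, 5))
        scores = model.decision_function(Xq)
        for i in range(100):
            for c in range(3):
                mu = model.means_[c]
                oracle = (
                    Xq[i] @ prec @ mu - 0.5 * mu @ prec @ mu + np.log(1 / 3)
                )
                assert scores[i, c] == pytest.approx(oracle, rel=1e-9)

    def test_agrees_with_sklearn_reference(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (200, 6)) + np.repeat(rng.normal(0, 2, (4, 6)), 50, axis=0)
        y = np.repeat([0, 1, 2, 3], 50)
        mine = train_lda(X, y, reg=1e-10)
        ref = LinearDiscriminantAnalysis().fit(X, y)
        Xq = rng.normal(0, 2, (500, 6))
        assert (mine.predict(Xq) == ref.predict(Xq)).mean() >= 0.98

    def test_shape_and_degenerate_errors(self):
        rng = np.random.default_rng(6)
        X, y = _two_gaussians(rng)
        model = train_lda(X, y)
        with pytest.raises(ParameterError):
            model.decision_function(np.zeros((3, 7)))
        with pytest.raises(ParameterError):
            train_lda(X, np.zeros(100))  # single class
        with pytest.raises(np.linalg.LinAlgError):
            ShrinkageLDA(reg=0.0).fit(np.hstack([X, X]), y)

    def test_sklearn_estimator_contract(self):
        model = ShrinkageLDA(reg=1e-3)
        assert model.get_params() == {"reg": 1e-3, "priors": "uniform"}
        model.set_params(reg=1e-2)
        assert model.get_params()["reg"] == 1e-2


class TestPerformanceIndices:
    def test_perfect_diagonal(self):
        perf = performance_indices(np.diag([10, 10, 10]))
        for name in ("Acc", "S", "P", "SP"):
            assert (perf[name] == 1.0).all()

    def test_hand_computed_two_class_case(self):
        perf = performance_indices(np.array([[8, 2], [3, 7]]))
        assert perf.loc[0, ["TP", "FN", "FP", "TN"]].tolist() == [8, 2, 3, 7]
        assert perf.loc[0, "Acc"] == pytest.approx(0.75)
        assert perf.loc[0, "S"] == pytest.approx(0.8)
        assert perf.loc[0, "P"] == pytest.approx(8 / 11)
        assert perf.loc[0, "SP"] == pytest.approx(0.7)

    def test_never_predicted_class_has_missing_precision(self):
        conf = np.array([[5, 0, 0], [5, 0, 0], [5, 0, 5]])
        perf = performance_indices(conf)
        assert np.isnan(perf.loc[1, "P"])
        assert not np.isnan(perf.loc[0, "P"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            performance_indices(np.array([[1, -1], [0, 2]]))

    @given(
        arrays(np.int64, st.tuples(st.integers(2, 6), st.integers(2, 6)),
               elements=st.integers(0, 50)).filter(
            lambda m: m.shape[0] == m.shape[1] and m.sum() > 0
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_identities_on_random_confusions(self, conf):
        perf = performance_indices(conf)
        assert np.array_equal(perf["TP"] + perf["FN"], conf.sum(axis=1))
        assert np.array_equal(perf["TP"] + perf["FP"], conf.sum(axis=0))
        for name in ("Acc", "S", "P", "SP"):
            vals = perf[name].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()


class TestEvaluateIterated:
    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(7)
        X, y = _two_gaussians(rng, n=20, d1=3.0)
        a = evaluate_iterated(X, y, n_iter=20, seed=42)
        b = evaluate_iterated(X, y, n_iter=20, seed=42)
        assert np.array_equal(a.confusions, b.confusions)
        for name in ("Acc", "S", "P", "SP"):
            assert np.array_equal(a.indices[name], b.indices[name])

    def test_separable_classes_score_one(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(c * 50, 1, (20, 2)) for c in range(3)])
        y = np.repeat([0, 1, 2], 20)
        summary = evaluate_iterated(X, y, n_iter=30, seed=0)
        assert summary.macro("Acc") == 1.0
        assert summary.macro("S") == 1.0

    def test_identical_distributions_score_at_chance(self):
        rng = np.random.default_rng(9)
        k, n = 4, 40
        X = rng.normal(0, 1, (k * n, 3))
        y = np.repeat(np.arange(k), n)
        summary = evaluate_iterated(X, y, n_iter=200, seed=1)
        # label-independent features: per-class sensitivity ~ 1/k; the data
        # (not the iterations) limit the Monte-Carlo error
        se = np.sqrt(0.25 * 0.75 / (n * k))
        assert abs(summary.macro("S") - 1 / k) < 3 * se

    def test_unbalanced_classes_rejected(self):
        X = np.zeros((30, 2))
        y = np.array([0] * 10 + [1] * 20)
        with pytest.raises(BalanceError):
            evaluate_iterated(X, y, n_iter=2, seed=0)

    def test_train_validation_gap_small_on_separable(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(c * 8, 1, (30, 4)) for c in range(3)])
        y = np.repeat([0, 1, 2], 30)
        summary = evaluate_iterated(X, y, n_iter=50, seed=2, track_train=True)
        gap = np.nanmean(summary.train_indices["Acc"]) - np.nanmean(
            summary.indices["Acc"]
        )
        assert abs(gap) < 0.02

    def test_confusion_row_sums_equal_validation_counts(self):
        rng = np.random.default_rng(11)
        X, y = _two_gaussians(rng, n=20, d1=2.0)
        summary = evaluate_iterated(X, y, n_iter=5, seed=3)
        assert (summary.confusions.sum(axis=2) == 10).all()
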
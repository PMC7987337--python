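"""Weighted L1 logistic solver, cross-validation, and metric aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression

from xburden import (
    aggregate_confusion,
    class_weights,
    cross_validate,
    fit_weighted_lasso,
    lambda_max,
    rank_features,
)
from xburden.lasso import LassoModel, _objective, _sample_weights


def reference_objective(X, y, lam, weights=None):
    """The stated objective as a plain function of (beta0, beta)."""
    w = _sample_weights(np.asarray(y, float), weights)

    def f(params):
        b0, b = params[0], params[1:]
        eta = b0 + X @ b
        return np.mean(w * (np.logaddexp(0, eta) - y * eta)) + lam * np.abs(b).sum()

    return f


class TestClassWeights:
    def test_balanced(self):
        w = class_weights([0] * 78 + [1] * 78)
        assert w == {0: 1.0, 1: 1.0}

    def test_nine_to_one(self):
        w = class_weights([0] * 9 + [1])
        assert w[0] == pytest.approx(10 / 18)
        assert w[1] == pytest.approx(5.0)

    def test_study_arm_sizes(self):
        w = class_weights([1] * 79 + [0] * 77)
        assert w[1] == pytest.approx(156 / 158)
        assert w[0] == pytest.approx(156 / 154)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestSolver:
    def test_lambda_above_lambda_max_nulls_all_coefficients(self):
        rng = np.random.default_rng(0)
        X = (rng.random((40, 8)) < 0.3).astype(float)
        y = rng.integers(0, 2, 40).astype(float)
        lmax = lambda_max(X, y)
        m = fit_weighted_lasso(X, y, lmax * 1.000001)
        assert (m.coef == 0.0).all()
        # intercept equals the weighted log-odds
        w = _sample_weights(y, None)
        assert m.intercept == pytest.approx(
            np.log((w * y).sum() / (w * (1 - y)).sum()), abs=1e-6
        )

    def test_informative_column_shrinks_monotonically(self):
        """A positively associated column keeps a positive coefficient that
        shrinks as the penalty grows; verified against a brute-force
        two-parameter grid minimization."""
        X = np.zeros((20, 1))
        X[:8, 0] = 1.0
        y = np.r_[np.ones(8), np.zeros(12)]  # x=1 -> always case
        lmax = lambda_max(X, y)
        prev = 0.0
        for lam in (0.8 * lmax, 0.5 * lmax, 0.2 * lmax):  # decreasing penalty
            m = fit_weighted_lasso(X, y, lam)
            beta = float(m.coef.iloc[0])
            assert beta > prev > -1  # positive and growing as the penalty relaxes
            prev = beta
            # brute-force oracle on a (beta0, beta1) grid around the solution
            f = reference_objective(X, y, lam)
            b0s = np.linspace(m.intercept - 0.5, m.intercept + 0.5, 81)
            b1s = np.linspace(beta - 0.5, beta + 0.5, 81)
            vals = [f(np.array([b0, b1])) for b0 in b0s for b1 in b1s]
            assert m.objective <= min(vals) + 1e-8

    def test_unpenalized_matches_sklearn_weighted_logit(self):
        rng = np.random.default_rng(4)
        X = (rng.random((60, 3)) < 0.4).astype(float)
        logit = -1 + X @ np.array([1.0, -0.5, 0.3])
        y = (rng.random(60) < 1 / (1 + np.exp(-logit))).astype(float)
        m = fit_weighted_lasso(X, y, 0.0, tol=1e-12)
        ref = LogisticRegression(C=np.inf, class_weight="balanced",
                                 tol=1e-10, max_iter=10_000).fit(X, y)
        assert np.allclose(m.coef.to_numpy(), ref.coef_.ravel(), atol=1e-6)
        assert m.intercept == pytest.approx(float(ref.intercept_[0]), abs=1e-6)

    def test_equal_weights_equal_unweighted_objective(self):
        rng = np.random.default_rng(2)
        X = (rng.random((30, 4)) < 0.3).astype(float)
        y = rng.integers(0, 2, 30).astype(float)
        beta = rng.normal(size=4)
        eta = 0.3 + X @ beta
        unit = np.ones(30)
        assert _objective(eta, y, unit, beta, 0.05) == pytest.approx(
            np.mean(np.logaddexp(0, eta) - y * eta) + 0.05 * np.abs(beta).sum()
        )

    def test_sparsity_grows_with_penalty(self):
        rng = np.random.default_rng(8)
        X = (rng.random((50, 10)) < 0.3).astype(float)
        y = rng.integers(0, 2, 50).astype(float)
        lmax = lambda_max(X, y)
        nnz = [
            int((fit_weighted_lasso(X, y, f * lmax).coef != 0).sum())
            for f in (0.9, 0.5, 0.2, 0.05)
        ]
        assert nnz == sorted(nnz)

    def test_objective_matches_generic_convex_optimizer(self):
        """Coordinate-descent optimum agrees with Nelder-Mead on the same
        objective for random small instances."""
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 8:
            n, g = int(rng.integers(10, 31)), int(rng.integers(2, 6))
            X = (rng.random((n, g)) < 0.3).astype(float)
            y = rng.integers(0, 2, n).astype(float)
            if y.min() == y.max():
                continue
            lam = float(rng.uniform(0.005, 0.2))
            m = fit_weighted_lasso(X, y, lam)
            f = reference_objective(X, y, lam)
            ref = minimize(f, np.zeros(g + 1), method="Nelder-Mead",
                           options=dict(maxiter=20000, maxfev=40000,
                                        xatol=1e-10, fatol=1e-14))
            assert m.objective <= ref.fun + 1e-6
            checked += 1

    def test_invalid_inputs(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            fit_weighted_lasso(X, [0, 1, 2, 1], 0.1)
        with pytest.raises(ValueError):
            fit_weighted_lasso(X, [0, 1, 0, 1], -0.5)


class TestCrossValidate:
    def test_perfect_feature_gives_perfect_accuracy(self):
        X = np.zeros((40, 3))
        y = np.r_[np.ones(20), np.zeros(20)]
        X[:20, 0] = 1.0
        cv = cross_validate(X, y, n_folds=5, seed=0, grid_size=12, refit=False)
        assert cv.mean_accuracy.max() == 1.0
        assert cv.metrics["accuracy"] == 1.0

    def test_same_seed_reproduces_everything(self):
        rng = np.random.default_rng(10)
        X = (rng.random((60, 20)) < 0.1).astype(float)
        y = np.r_[np.ones(30), np.zeros(30)]
        cv1 = cross_validate(X, y, n_folds=5, seed=3, grid_size=8, refit=False)
        cv2 = cross_validate(X, y, n_folds=5, seed=3, grid_size=8, refit=False)
        assert cv1.chosen_lambda == cv2.chosen_lambda
        assert (cv1.fold_assignment == cv2.fold_assignment).all()
        assert np.array_equal(cv1.oof_prob, cv2.oof_prob)
        assert cv1.confusion == cv2.confusion

    def test_fold_label_composition_is_stratified(self):
        rng = np.random.default_rng(11)
        X = (rng.random((50, 5)) < 0.2).astype(float)
        y = np.r_[np.ones(25), np.zeros(25)]
        cv = cross_validate(X, y, n_folds=5, seed=1, grid_size=5, refit=False)
        for f in range(5):
            labels = cv.y[cv.fold_assignment == f]
            assert labels.sum() == 5  # 5 cases in each fold of 10

    def test_each_subject_predicted_once(self):
        rng = np.random.default_rng(12)
        X = (rng.random((30, 5)) < 0.3).astype(float)
        y = np.r_[np.ones(15), np.zeros(15)]
        cv = cross_validate(X, y, n_folds=3, seed=0, grid_size=5, refit=False)
        c = cv.confusion
        assert c["TP"] + c["FP"] + c["TN"] + c["FN"] == 30

    def test_too_many_folds_errors(self):
        X = np.zeros((10, 2))
        y = np.r_[np.ones(2), np.zeros(8)]
        X[:2, 0] = 1
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, n_folds=5, seed=0)


class TestAggregateConfusion:
    def test_textbook_counts(self):
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        prob = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.2, 0.3]  # TP=3 FN=1 FP=1 TN=3
        confusion, metrics = aggregate_confusion(y, prob)
        assert confusion == {"TP": 3, "FP": 1, "TN": 3, "FN": 1}
        assert metrics["sensitivity"] == pytest.approx(0.75)
        assert metrics["specificity"] == pytest.approx(0.75)
        assert metrics["accuracy"] == pytest.approx(0.75)

    def test_all_equal_probabilities_auc_half(self):
        _, metrics = aggregate_confusion([1, 1, 0, 0], [0.4] * 4)
        assert metrics["roc_auc"] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        ("labels", "expected_auc"),
        [((1, 1, 0, 0), 1.0), ((0, 1, 1, 0), 0.5)],
    )
    def test_auc_by_pair_enumeration(self, labels, expected_auc):
        prob = [0.9, 0.8, 0.3, 0.2]
        _, metrics = aggregate_confusion(list(labels), prob)
        # oracle: fraction of (positive, negative) pairs correctly ordered
        pos = [p for p, l in zip(prob, labels) if l == 1]
        neg = [p for p, l in zip(prob, labels) if l == 0]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
        assert metrics["roc_auc"] == pytest.approx(np.mean(pairs))
        assert metrics["roc_auc"] == pytest.approx(expected_auc)

    def test_zero_denominator_reported_missing(self):
        _, metrics = aggregate_confusion([0, 0], [0.1, 0.2])
        assert np.isnan(metrics["precision"])
        assert np.isnan(metrics["sensitivity"])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_confusion([], [])


class TestRankFeatures:
    @staticmethod
    def model_with(coefs: dict[str, float]) -> LassoModel:
        return LassoModel(
            intercept=0.0,
            coef=pd.Series(coefs),
            lam=0.1,
            weights={0: 1.0, 1: 1.0},
            tol=1e-7,
            n_iter=1,
            objective=0.0,
        )

    def test_all_zero_model_gives_empty_ranking(self):
        rk = rank_features(self.model_with({"A": 0.0, "B": 0.0}))
        assert rk.empty

    def test_direction_and_order(self):
        rk = rank_features(self.model_with({"A": 0.8, "B": -0.3, "C": 0.0}))
        assert rk["gene"].tolist() == ["A", "B"]
        assert rk["direction"].tolist() == ["susceptible", "protective"]

    def test_magnitude_ties_break_lexicographically(self):
        rk = rank_features(self.model_with({"Z": 0.5, "A": -0.5, "M": 0.7}))
        assert rk["gene"].tolist() == ["M", "A", "Z"]
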
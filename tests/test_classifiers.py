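import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.optimize import minimize
from scipy.stats import norm

from confsel.classifiers import (
    GNBModel,
    KNNConfig,
    LRModel,
    fit_gaussian_nb,
    fit_logistic,
    logistic_cost_grad,
    predict_gaussian_nb,
    predict_knn,
    predict_logistic,
)
from confsel.datasets import LabeledDataset
from confsel.exceptions import DimensionMismatchError, SingleClassError


def _make(X, y):
    return LabeledDataset(features=np.asarray(X, float),
                          labels=np.asarray(y, int))


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

class TestFitLogistic:
    def test_symmetric_1d_zero_intercept(self):
        X = np.r_[np.full(50, -1.0), np.full(50, 1.0)].reshape(-1, 1)
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        model = fit_logistic(_make(X, y), C=5.0, standardize=False)
        assert abs(model.intercept) < 1e-3
        assert model.weights[0] > 0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30).astype(float)
        theta = rng.normal(size=5)
        C = 5.0
        _, grad = logistic_cost_grad(theta, X, y, C)
        h = 1e-6
        fd = np.empty_like(theta)
        for j in range(theta.size):
            e = np.zeros_like(theta)
            e[j] = h
            cp, _ = logistic_cost_grad(theta + e, X, y, C)
            cm, _ = logistic_cost_grad(theta - e, X, y, C)
            fd[j] = (cp - cm) / (2 * h)
        assert np.max(np.abs(grad - fd)) < 1e-5

    def test_cost_at_least_as_low_as_scipy(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(-1, 1, (40, 3)), rng.normal(1, 1, (40, 3))])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        ds = _make(X, y)
        model = fit_logistic(ds, C=5.0, standardize=False, tol=1e-12)
        ref = minimize(
            lambda t: logistic_cost_grad(t, X, y.astype(float), 5.0)[0],
            np.zeros(4), jac=lambda t: logistic_cost_grad(
                t, X, y.astype(float), 5.0)[1],
            method="L-BFGS-B", options={"ftol": 1e-15, "gtol": 1e-12},
        )
        assert model.final_cost <= ref.fun + 1e-6

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            fit_logistic(_make(np.ones((5, 1)), np.zeros(5, int)))

    def test_deterministic(self, separable_dataset):
        a = fit_logistic(separable_dataset, C=5.0)
        b = fit_logistic(separable_dataset, C=5.0)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.intercept == b.intercept

    def test_convergence_reported(self, separable_dataset):
        model = fit_logistic(separable_dataset, C=5.0, max_iter=2000)
        assert model.converged
        few = fit_logistic(separable_dataset, C=5.0, max_iter=2)
        assert not few.converged and few.n_iter == 2

    def test_cost_monotone_under_small_fixed_step(self):
        # property: gradient descent with a small fixed step never increases cost
        rng = np.random.default_rng(3)
        for trial in range(5):
            X = rng.normal(size=(25, 3))
            y = rng.integers(0, 2, 25).astype(float)
            theta = np.zeros(4)
            cost, grad = logistic_cost_grad(theta, X, y, 5.0)
            for _ in range(50):
                theta = theta - 0.05 * grad
                new_cost, grad = logistic_cost_grad(theta, X, y, 5.0)
                assert new_cost <= cost + 1e-12
                cost = new_cost


class TestPredictLogistic:
    def test_all_zero_weights_gives_half(self):
        model = LRModel(intercept=0.0, weights=np.zeros(3), C=5.0,
                        standardize=False)
        proba, labels = predict_logistic(model, np.random.default_rng(0)
                                         .normal(size=(4, 3)))
        np.testing.assert_array_equal(proba, 0.5)
        np.testing.assert_array_equal(labels, 1)  # p >= threshold convention

    def test_saturation_no_overflow(self):
        model = LRModel(intercept=0.0, weights=np.array([1.0]), C=5.0,
                        standardize=False)
        proba, _ = predict_logistic(model, np.array([[50.0]]))
        assert proba[0] >= 1 - 1e-20  # saturates to 1.0 in float64
        assert np.isfinite(proba[0])
        proba, _ = predict_logistic(model, np.array([[-800.0]]))
        assert proba[0] == 0.0  # underflow, not overflow error

    def test_matches_closed_form(self):
        model = LRModel(intercept=0.3, weights=np.array([1.5, -2.0]), C=5.0,
                        standardize=False)
        X = np.array([[0.0, 0.0], [1.0, 1.0], [-2.0, 0.5]])
        proba, _ = predict_logistic(model, X)
        z = 0.3 + X @ np.array([1.5, -2.0])
        np.testing.assert_allclose(proba, 1 / (1 + np.exp(-z)), atol=1e-12)

    def test_dimension_mismatch(self):
        model = LRModel(intercept=0.0, weights=np.zeros(3), C=5.0)
        with pytest.raises(DimensionMismatchError):
            predict_logistic(model, np.zeros((2, 4)))

    def test_json_round_trip(self, separable_dataset, tmp_path):
        model = fit_logistic(separable_dataset)
        p = tmp_path / "lr.json"
        model.to_json(p)
        back = LRModel.from_json(p)
        np.testing.assert_array_equal(back.weights, model.weights)
        X = separable_dataset.features[:5]
        np.testing.assert_array_equal(
            predict_logistic(back, X)[0], predict_logistic(model, X)[0])


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

class TestFitGaussianNB:
    def test_two_point_moments(self):
        ds = _make([[0.0], [2.0], [5.0]], [0, 0, 1])
        model = fit_gaussian_nb(ds)
        assert model.means[0, 0] == 1.0
        assert model.variances[0, 0] == 1.0  # population variance

    def test_balanced_priors(self):
        ds = _make([[0.0], [1.0], [2.0], [3.0]], [0, 0, 1, 1])
        model = fit_gaussian_nb(ds)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])
        assert abs(model.priors.sum() - 1.0) < 1e-12

    def test_constant_feature_clamped(self):
        ds = _make([[1.0, 0.0], [1.0, 2.0], [1.0, 5.0], [1.0, 9.0]],
                   [0, 0, 1, 1])
        model = fit_gaussian_nb(ds, var_floor=1e-6)
        assert model.variances[0, 0] == 1e-6
        post, _ = predict_gaussian_nb(model, np.array([[1.0, 3.0]]))
        assert np.all(np.isfinite(post))

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            fit_gaussian_nb(_make(np.ones((4, 1)), np.ones(4, int)))


class TestPredictGaussianNB:
    def test_symmetric_tie_goes_to_class_zero(self):
        model = GNBModel(
            priors=np.array([0.5, 0.5]),
            means=np.array([[-1.0], [1.0]]),
            variances=np.array([[1.0], [1.0]]),
            var_floor=1e-12,
        )
        post, labels = predict_gaussian_nb(model, np.array([[0.0]]))
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-12)
        assert labels[0] == 0

    def test_brute_force_bayes_oracle(self):
        # explicit density products with explicit normalizer P(x)
        model = GNBModel(
            priors=np.array([0.3, 0.7]),
            means=np.array([[-1.0, 2.0], [1.5, -0.5]]),
            variances=np.array([[0.5, 2.0], [1.2, 0.8]]),
            var_floor=1e-12,
        )
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2))
        post, _ = predict_gaussian_nb(model, X)
        for i, x in enumerate(X):
            joint = np.empty(2)
            for cls in (0, 1):
                dens = norm.pdf(x, loc=model.means[cls],
                                scale=np.sqrt(model.variances[cls]))
                joint[cls] = model.priors[cls] * np.prod(dens)
            expected = joint / joint.sum()
            np.testing.assert_allclose(post[i], expected, atol=1e-10)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(8)
        ds = _make(rng.normal(size=(50, 3)), rng.integers(0, 2, 50))
        model = fit_gaussian_nb(ds)
        post, _ = predict_gaussian_nb(model, rng.normal(size=(200, 3)) * 100)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_prior_monotonicity(self):
        means = np.array([[-1.0], [1.0]])
        variances = np.array([[1.0], [1.0]])
        x = np.array([[0.3]])
        last = -1.0
        for p1 in (0.1, 0.3, 0.5, 0.7, 0.9):
            model = GNBModel(priors=np.array([1 - p1, p1]), means=means,
                             variances=variances, var_floor=1e-12)
            post, _ = predict_gaussian_nb(model, x)
            assert post[0, 1] > last
            last = post[0, 1]

    def test_dimension_mismatch(self):
        model = GNBModel(priors=np.array([0.5, 0.5]),
                         means=np.zeros((2, 2)), variances=np.ones((2, 2)),
                         var_floor=1e-12)
        with pytest.raises(DimensionMismatchError):
            predict_gaussian_nb(model, np.zeros((1, 3)))

    def test_json_round_trip(self, tmp_path):
        ds = _make(np.random.default_rng(1).normal(size=(30, 2)),
                   np.r_[np.zeros(20, int), np.ones(10, int)])
        model = fit_gaussian_nb(ds)
        back = GNBModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.means, model.means)
        np.testing.assert_array_equal(back.variances, model.variances)


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

class TestPredictKNN:
    def test_k1_exact_match(self):
        ds = _make([[0.0, 0.0], [5.0, 5.0]], [0, 1])
        _, labels = predict_knn(ds, np.array([[5.0, 5.0]]),
                                KNNConfig(k=1, standardize=False))
        assert labels[0] == 1

    def test_exhaustive_sort_oracle(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0],
                        [3.0, 3.0], [4.0, 4.0]])
        y = np.array([0, 0, 1, 1, 1])
        ds = _make(pts, y)
        query = np.array([[0.5, 0.5]])
        d2 = np.sum((pts - query) ** 2, axis=1)
        order = np.argsort(d2, kind="stable")[:3]
        expected = int(np.sum(y[order]) * 2 > 3)
        _, labels = predict_knn(ds, query, KNNConfig(k=3, standardize=False))
        assert labels[0] == expected == 0

    def test_k_equals_n_gives_majority(self):
        ds = _make(np.arange(10.0).reshape(5, 2), [0, 0, 0, 1, 1])
        _, labels = predict_knn(ds, np.array([[100.0, 100.0]]),
                                KNNConfig(k=5, standardize=False))
        assert labels[0] == 0

    def test_vote_tie_broken_by_nearest(self):
        ds = _make([[0.0], [10.0]], [1, 0])
        _, labels = predict_knn(ds, np.array([[1.0]]),
                                KNNConfig(k=2, standardize=False))
        assert labels[0] == 1  # nearest neighbor has label 1

    def test_distance_tie_lower_index_wins(self):
        ds = _make([[1.0], [-1.0]], [0, 1])
        _, labels = predict_knn(ds, np.array([[0.0]]),
                                KNNConfig(k=1, standardize=False))
        assert labels[0] == 0  # row 0 wins the exact distance tie

    def test_k_too_large_raises(self):
        ds = _make([[0.0], [1.0]], [0, 1])
        with pytest.raises(ValueError):
            predict_knn(ds, np.array([[0.0]]), KNNConfig(k=3))

    def test_dimension_mismatch(self, tiny_dataset):
        with pytest.raises(DimensionMismatchError):
            predict_knn(tiny_dataset, np.zeros((1, 5)), KNNConfig(k=2))

    @settings(max_examples=30, deadline=None)
    @given(
        X=hnp.arrays(float, (12, 3),
                     elements=st.floats(-10, 10, allow_nan=False)),
        perm_seed=st.integers(0, 1000),
    )
    def test_feature_permutation_invariance(self, X, perm_seed):
        y = np.array([0, 1] * 6)
        query = X[:4] + 0.25
        perm = np.random.default_rng(perm_seed).permutation(3)
        cfg = KNNConfig(k=3, standardize=False)
        _, a = predict_knn(_make(X, y), query, cfg)
        _, b = predict_knn(_make(X[:, perm], y), query[:, perm], cfg)
        np.testing.assert_array_equal(a, b)

    def test_score_is_vote_fraction(self):
        ds = _make([[0.0], [0.1], [0.2], [10.0], [10.1]], [1, 1, 0, 0, 0])
        scores, _ = predict_knn(ds, np.array([[0.0]]),
                                KNNConfig(k=3, standardize=False))
        assert scores[0] == pytest.approx(2 / 3)


class TestSeparableTraining:
    """All three learners nail a linearly separable training set."""

    def _se_sp(self, y_true, y_pred):
        tp = np.sum((y_true == 1) & (y_pred == 1))
        tn = np.sum((y_true == 0) & (y_pred == 0))
        return tp / np.sum(y_true == 1), tn / np.sum(y_true == 0)

    def test_all_classifiers_perfect(self, separable_dataset):
        ds = separable_dataset
        lr = fit_logistic(ds, C=5.0)
        _, pred_lr = predict_logistic(lr, ds.features)
        gnb = fit_gaussian_nb(ds)
        _, pred_gnb = predict_gaussian_nb(gnb, ds.features)
        _, pred_knn = predict_knn(ds, ds.features, KNNConfig(k=1))
        for pred in (pred_lr, pred_gnb, pred_knn):
            se, sp = self._se_sp(ds.labels, pred)
            assert se == 1.0 and sp == 1.0
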
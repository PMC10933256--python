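"""Prediction tests: RMSE, fold construction, both model families,
repeated cross-validation and the permutation test."""

import numpy as np
import pytest
import scipy.optimize
from sklearn.base import clone
from sklearn.linear_model import Ridge

from dyadsat.prediction import (
    ModelSpec,
    SimilarityRegressor,
    fit_model,
    make_folds,
    permutation_test,
    repeated_cv,
    rmse,
)

RNG = np.random.default_rng(5)


class TestRmse:
    def test_identical_vectors_give_zero(self):
        v = RNG.normal(size=10)
        assert rmse(v, v) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_absolute_homogeneity(self):
        obs = RNG.normal(size=8)
        pred = RNG.normal(size=8)
        assert rmse(-2.5 * obs, -2.5 * pred) == pytest.approx(2.5 * rmse(obs, pred))

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestMakeFolds:
    def test_29_items_in_10_folds_gives_train_sizes_26_or_27(self):
        folds = make_folds(29, 10, np.random.default_rng(0))
        sizes = np.bincount(folds, minlength=10)
        assert sorted(sizes) == [2] + [3] * 9
        assert set(29 - sizes) == {26, 27}

    def test_partition_is_disjoint_and_complete(self):
        folds = make_folds(17, 5, np.random.default_rng(1))
        assert folds.shape == (17,)
        assert set(folds) == set(range(5))

    def test_different_rng_states_differ(self):
        a = make_folds(29, 10, np.random.default_rng(2))
        b = make_folds(29, 10, np.random.default_rng(3))
        assert not np.array_equal(a, b)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 10, np.random.default_rng(0))


class TestFitModel:
    def test_constant_target_svr_has_zero_weights(self):
        X = RNG.normal(size=(12, 4))
        model = fit_model(ModelSpec(), X, np.full(12, 3.0))
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-9)
        assert abs(model.intercept - 3.0) <= 0.1 + 1e-9  # within epsilon

    def test_ridge_small_alpha_matches_ols(self):
        X = RNG.normal(size=(30, 3))
        y = RNG.normal(size=30)
        model = fit_model(ModelSpec(family="ridge", alpha=1e-10), X, y)
        xi = np.column_stack([np.ones(30), X])
        beta = np.linalg.lstsq(xi, y, rcond=None)[0]
        np.testing.assert_allclose(model.weights, beta[1:], atol=1e-8)
        np.testing.assert_allclose(model.intercept, beta[0], atol=1e-8)

    @pytest.mark.parametrize("n,p", [(10, 25), (25, 10)])
    def test_ridge_matches_sklearn_in_both_regimes(self, n, p):
        X = RNG.normal(size=(n, p))
        y = RNG.normal(size=n)
        model = fit_model(ModelSpec(family="ridge", alpha=1.3), X, y)
        sk = Ridge(alpha=1.3).fit(X, y)
        np.testing.assert_allclose(model.weights, sk.coef_, atol=1e-8)
        np.testing.assert_allclose(model.intercept, sk.intercept_, atol=1e-8)

    def test_svr_objective_matches_qp_oracle(self):
        """Primal epsilon-SVR objective vs a generic constrained QP solve."""
        n, p, C, eps = 8, 3, 1.0, 0.1
        X = RNG.normal(size=(n, p))
        y = X @ np.array([0.5, -1.0, 0.2]) + 0.1 * RNG.normal(size=n)

        def objective(v):
            w = v[:p]
            return 0.5 * w @ w + C * np.sum(v[p + 1:])

        def residual_constraints(v):
            w, b = v[:p], v[p]
            xi = v[p + 1: p + 1 + n]
            xi_star = v[p + 1 + n:]
            pred = X @ w + b
            return np.concatenate(
                [eps + xi - (y - pred), eps + xi_star - (pred - y)]
            )

        v0 = np.zeros(p + 1 + 2 * n)
        bounds = [(None, None)] * (p + 1) + [(0, None)] * (2 * n)
        sol = scipy.optimize.minimize(
            objective,
            v0,
            method="SLSQP",
            bounds=bounds,
            constraints={"type": "ineq", "fun": residual_constraints},
            options={"maxiter": 500, "ftol": 1e-12},
        )
        assert sol.success

        model = fit_model(ModelSpec(tol=1e-10), X, y)
        slack_hi = np.maximum(0, (y - model.predict(X)) - eps)
        slack_lo = np.maximum(0, (model.predict(X) - y) - eps)
        primal = 0.5 * model.weights @ model.weights + C * np.sum(
            slack_hi + slack_lo
        )
        assert abs(primal - sol.fun) < 1e-6

    def test_nonfinite_input_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_model(ModelSpec(), X, np.ones(4))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(family="forest")
        with pytest.raises(ValueError):
            ModelSpec(C=0.0)


def test_similarity_regressor_is_sklearn_compatible():
    est = SimilarityRegressor(family="ridge", alpha=0.7)
    assert clone(est).get_params()["alpha"] == 0.7
    X = RNG.normal(size=(15, 4))
    y = RNG.normal(size=15)
    est.fit(X, y)
    assert est.coef_.shape == (4,)
    assert np.all(np.isfinite(est.predict(X)))


def test_standardize_flag_keeps_original_space_predictions():
    X = RNG.normal(size=(20, 3)) * np.array([1.0, 10.0, 0.1])
    y = RNG.normal(size=20)
    plain = fit_model(ModelSpec(family="ridge"), X, y)
    scaled = fit_model(ModelSpec(family="ridge", standardize=True), X, y)
    # same model class, different penalty geometry: predictions finite and
    # weights expressed on the original feature scale in both cases
    assert np.all(np.isfinite(scaled.predict(X)))
    assert plain.weights.shape == scaled.weights.shape


class TestRepeatedCV:
    def test_reproducible_under_fixed_seed(self):
        X = RNG.normal(size=(20, 6))
        y = RNG.normal(size=20)
        a = repeated_cv(X, y, ModelSpec(family="ridge"), k=5, n_repeats=3, seed=9)
        b = repeated_cv(X, y, ModelSpec(family="ridge"), k=5, n_repeats=3, seed=9)
        np.testing.assert_array_equal(a.per_repeat_rmse, b.per_repeat_rmse)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)

    def test_every_item_predicted_once_per_repeat(self):
        X = RNG.normal(size=(29, 5))
        y = RNG.normal(size=29)
        res = repeated_cv(X, y, ModelSpec(family="ridge"), k=10, n_repeats=4, seed=0)
        for r in range(4):
            assert set(res.fold_assignments[r]) == set(range(10))
        assert res.mean_rmse == pytest.approx(res.per_repeat_rmse.mean())

    def test_noiseless_linear_target_recovered_by_ridge(self):
        X = RNG.normal(size=(40, 5))
        w = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = X @ w
        res = repeated_cv(
            X, y, ModelSpec(family="ridge", alpha=1e-8), k=10, n_repeats=3, seed=1
        )
        assert res.mean_rmse < 0.05 * y.std()

    def test_out_of_fold_discipline_poisoned_label(self):
        """A pair's own label must not influence its prediction."""
        X = RNG.normal(size=(18, 4))
        y = RNG.normal(size=18)
        res = repeated_cv(X, y, ModelSpec(family="ridge"), k=6, n_repeats=2, seed=3)
        y_poison = y.copy()
        y_poison[7] += 100.0
        res_p = repeated_cv(
            X, y_poison, ModelSpec(family="ridge"), k=6, n_repeats=2, seed=3
        )
        np.testing.assert_allclose(
            res.predictions[:, 7], res_p.predictions[:, 7], atol=1e-10
        )

    def test_ridge_predictions_continuous_in_alpha(self):
        X = RNG.normal(size=(20, 4))
        y = RNG.normal(size=20)
        alphas = [0.5, 0.5001, 1.0]
        preds = [
            repeated_cv(
                X, y, ModelSpec(family="ridge", alpha=a), k=5, n_repeats=1, seed=4
            ).predictions[0]
            for a in alphas
        ]
        near = np.abs(preds[1] - preds[0]).max()
        far = np.abs(preds[2] - preds[0]).max()
        assert near < 1e-3
        assert near < far


class TestPermutationTest:
    def test_null_distribution_length_and_p_range(self):
        X = RNG.normal(size=(16, 4))
        y = RNG.normal(size=16)
        res = permutation_test(
            X, y, ModelSpec(family="ridge"), k=4, n_repeats=2, n_perm=25, seed=0
        )
        assert res.null_rmses.shape == (25,)
        assert 0.0 <= res.p_value <= 1.0
        count = int(np.sum(res.null_rmses <= res.mean_rmse))
        assert res.p_value == count / 25
        assert res.p_smoothed == pytest.approx((1 + count) / 26)

    def test_strong_signal_beats_every_null(self):
        X = RNG.normal(size=(24, 3))
        y = X @ np.array([2.0, -1.5, 1.0])  # noiseless planted signal
        res = permutation_test(
            X, y, ModelSpec(family="ridge", alpha=1e-6),
            k=6, n_repeats=2, n_perm=50, seed=1,
        )
        assert res.p_value == 0.0

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones((4, 2)), np.ones(4), n_perm=0)


def test_mean_rmse_monotone_in_planted_effect_size():
    """Stronger planted signal yields lower cross-validated error (full chain).

    Normalized by the target SD so the none/weak/strong regimes are
    comparable; averaged over matched seeds to suppress cohort-level
    Monte-Carlo noise.
    """
    from conftest import pipeline_features
    from dyadsat.synthetic import SyntheticConfig, generate_cohort

    seeds = (21, 3, 7)
    means = []
    for scale in (0.0, 0.6, 2.0):
        vals = []
        for seed in seeds:
            cfg = SyntheticConfig(
                seed=seed, signal_scale=scale, intercept=5.7 if scale else 6.0
            )
            X, y = pipeline_features(generate_cohort(cfg))
            res = repeated_cv(
                X, y, ModelSpec(family="ridge"), k=10, n_repeats=3, seed=5
            )
            vals.append(res.mean_rmse / y.std())
        means.append(np.mean(vals))
    assert means[2] <= means[1] + 0.02
    assert means[1] <= means[0] + 0.02
    assert means[2] < means[0]
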
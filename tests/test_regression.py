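"""Streamwise VIF-corrected selection and its closed-form pieces."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trinet import (SparseLinearModel, StreamwiseVifRegressor,
                    ValidationError, VifParams, adjusted_r2,
                    evaluate_l0_objective, fit_streamwise, vif_correction)
from trinet.regression import RHO_FLOOR


class TestAdjustedR2:
    def test_perfect_fit_is_one(self):
        assert adjusted_r2(0.0, 5.0, 10, 3) == 1.0

    def test_no_predictors_equals_r2(self):
        assert adjusted_r2(2.0, 10.0, 25, 0) == pytest.approx(0.8)

    def test_hand_arithmetic(self):
        # R^2 = 0.9, n = 10, k = 3 -> 1 - 0.1 * 9 / 6
        assert adjusted_r2(1.0, 10.0, 10, 3) == pytest.approx(0.85)

    def test_undefined_when_df_exhausted(self):
        with pytest.raises(ValidationError):
            adjusted_r2(1.0, 10.0, 5, 4)

    @given(st.integers(0, 5), st.integers(0, 5))
    def test_strictly_decreasing_in_model_size(self, k1, k2):
        n, rss, tss = 20, 3.0, 10.0
        if k1 == k2:
            return
        lo, hi = sorted((k1, k2))
        assert adjusted_r2(rss, tss, n, hi) < adjusted_r2(rss, tss, n, lo)


class TestL0Objective:
    def test_zero_beta_gives_squared_norm(self):
        y = np.array([3.0, 4.0])
        X = np.eye(2)
        assert evaluate_l0_objective(y, X, np.zeros(2), 1.0) == 25.0

    def test_hand_case(self):
        y = np.array([1.0, 2.0])
        assert evaluate_l0_objective(y, np.eye(2), np.array([1.0, 0.0]),
                                     1.0) == 5.0

    def test_interpolating_beta_with_no_penalty(self):
        y = np.array([1.0, 2.0])
        assert evaluate_l0_objective(y, np.eye(2), y, 0.0) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            evaluate_l0_objective(np.ones(3), np.eye(2), np.ones(2), 0.0)


class TestVifCorrection:
    def test_empty_support_no_inflation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        assert vif_correction(x, np.empty((50, 0)), np.arange(50)) == 1.0

    def test_orthogonal_candidate(self):
        n = 40
        x = np.zeros(n)
        x[: n // 2] = 1.0
        x -= x.mean()
        z = np.zeros(n)
        z[::2] = 1.0
        z -= z.mean()
        z -= (z @ x) / (x @ x) * x  # exactly orthogonal, both centered
        rho = vif_correction(x, z[:, None], np.arange(n))
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_collinear_duplicate_hits_floor(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60)
        rho = vif_correction(x, x[:, None], np.arange(60))
        assert rho == RHO_FLOOR

    def test_presample_estimate_tracks_full_data(self):
        rng = np.random.default_rng(2)
        n = 400
        z = rng.standard_normal(n)
        x = 0.8 * z + 0.6 * rng.standard_normal(n)
        presample = rng.choice(n, 150, replace=False)
        rho_pre = vif_correction(x, z[:, None], presample)
        rho_full = vif_correction(x, z[:, None], np.arange(n))
        assert rho_pre == pytest.approx(rho_full, abs=0.15)
        assert 0.2 < rho_pre < 0.6  # true residual fraction is 0.36

    def test_tiny_presample_falls_back_to_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        Z = rng.standard_normal((20, 5))
        assert vif_correction(x, Z, np.arange(4)) == 1.0


def _sparse_problem(seed, n=200, p=50, support=(3, 7), coef=5.0,
                    noise_sd=0.1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = sum(coef * X[:, j] for j in support) + rng.normal(0, noise_sd, n)
    return X, y


class TestStreamwiseFit:
    def test_noiseless_single_predictor(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 20))
        y = X[:, 7].copy()
        est = StreamwiseVifRegressor(random_state=0).fit(X, y)
        assert list(est.support_) == [7]
        assert est.r2_ == pytest.approx(1.0, abs=1e-12)
        assert est.adj_r2_ == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_true_pair_and_matches_best_subset(self, seed):
        X, y = _sparse_problem(seed)
        est = StreamwiseVifRegressor(random_state=seed).fit(X, y)
        assert sorted(est.support_) == [3, 7]
        # independent oracle: exhaustive search over all pairs
        best = min(itertools.combinations(range(X.shape[1]), 2),
                   key=lambda pair: np.linalg.lstsq(
                       np.column_stack([X[:, pair[0]], X[:, pair[1]],
                                        np.ones(len(y))]),
                       y, rcond=None)[1][0])
        assert sorted(est.support_) == sorted(best)

    def test_matches_exhaustive_best_subset_small_p(self):
        X, y = _sparse_problem(11, n=100, p=12, support=(2, 9),
                               coef=3.0, noise_sd=0.1)
        est = StreamwiseVifRegressor(random_state=11).fit(X, y)
        best = min(itertools.combinations(range(12), 2),
                   key=lambda pair: float(np.linalg.lstsq(
                       np.column_stack([X[:, list(pair)], np.ones(100)]),
                       y, rcond=None)[1][0]))
        assert sorted(est.support_) == sorted(best) == [2, 9]

    def test_null_selects_almost_nothing(self):
        """Permutation-null: mean false selections below 1 over 50 seeds."""
        sizes = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((100, 30))
            y = rng.standard_normal(100)
            est = StreamwiseVifRegressor(random_state=seed).fit(X, y)
            sizes.append(len(est.support_))
            assert len(est.support_) <= 2
        assert np.mean(sizes) < 1.0

    def test_deterministic_given_seed(self):
        X, y = _sparse_problem(5)
        a = StreamwiseVifRegressor(random_state=42).fit(X, y)
        b = StreamwiseVifRegressor(random_state=42).fit(X, y)
        assert list(a.support_) == list(b.support_)
        np.testing.assert_array_equal(a.coef_, b.coef_)
        assert a.adj_r2_ == b.adj_r2_

    def test_refit_objective_equals_rss(self):
        X, y = _sparse_problem(6)
        est = StreamwiseVifRegressor(random_state=6, lambda0=0.0).fit(X, y)
        resid = y - est.predict(X)
        # the intercept is absorbed before evaluating the penalized RSS
        np.testing.assert_allclose(
            evaluate_l0_objective(y - est.intercept_, X, est.coef_, 0.0),
            est.rss_, rtol=1e-10)
        np.testing.assert_allclose(est.objective(), float(resid @ resid),
                                   rtol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_orthonormal_strong_signal_recovery(self, seed):
        """Exact support recovery on near-orthogonal designs, k_true = 4."""
        rng = np.random.default_rng(seed)
        n, p, true = 200, 100, [5, 17, 42, 73]
        X = rng.standard_normal((n, p))
        y = sum(2.0 * X[:, j] for j in true) + rng.normal(0, 0.5, n)
        est = StreamwiseVifRegressor(random_state=seed).fit(X, y)
        assert sorted(est.support_) == true

    def test_predict_and_score(self):
        X, y = _sparse_problem(8)
        est = StreamwiseVifRegressor(random_state=8).fit(X, y)
        assert est.score(X, y) == pytest.approx(est.r2_, abs=1e-12)

    def test_coefficients_on_original_scale(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((150, 10))
        X[:, 4] *= 100.0  # un-standardized predictor
        y = 0.03 * X[:, 4] + rng.normal(0, 0.1, 150)
        est = StreamwiseVifRegressor(random_state=9).fit(X, y)
        assert list(est.support_) == [4]
        assert est.coef_[4] == pytest.approx(0.03, abs=0.005)

    def test_sklearn_param_protocol(self):
        est = StreamwiseVifRegressor(payout=0.1)
        assert est.get_params()["payout"] == 0.1
        est.set_params(max_passes=3)
        assert est.max_passes == 3
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            StreamwiseVifRegressor().fit(np.ones((2, 3)), np.ones(2))
        with pytest.raises(ValidationError):
            StreamwiseVifRegressor().fit(np.ones((5, 2)), np.ones(4))
        with pytest.raises(ValidationError):
            VifParams(initial_wealth=1.5)


class TestFitStreamwiseWrapper:
    def test_returns_identified_sparse_model(self):
        X, y = _sparse_problem(12, p=20, support=(3, 7))
        ids = [f"g{j}" for j in range(20)]
        model = fit_streamwise(y, X, VifParams(seed=12),
                               predictor_ids=ids, target_id="target")
        assert isinstance(model, SparseLinearModel)
        assert sorted(model.support) == ["g3", "g7"]
        assert model.k == 2
        assert model.adj_r2 <= model.r2 <= 1.0
        assert model.adj_r2 > 0.99

    def test_target_in_support_rejected(self):
        with pytest.raises(ValidationError):
            SparseLinearModel("t", ["t"], [1.0])
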
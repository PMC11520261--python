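"""Nuisance models: likelihood oracles, baselines, adaptive-LASSO behaviour."""

import numpy as np
import pandas as pd
import pytest

from drclaims._coxlik import breslow_baseline, cox_partial_gradient, cox_partial_loglik
from drclaims.exceptions import DataError
from drclaims.nuisance import (
    fit_adaptive_lasso_cox,
    fit_adaptive_lasso_logistic,
    fit_cox_mle,
    fit_logistic_mle,
    intercept_only_cox,
    predict_propensity,
    predict_survival,
)


def brute_force_cox_loglik(beta, X, time, event):
    """Risk-set enumeration of the Breslow partial likelihood (<= 6 subjects)."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        denom = sum(np.exp(X[j] @ beta) for j in risk)
        ll += X[i] @ beta - np.log(denom)
    return ll


class TestCoxLikelihoodOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglik_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 6, 2
        X = rng.normal(size=(n, p))
        time = rng.exponential(1.0, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        for beta in ([0.0, 0.0], [0.5, -0.3], [1.2, 0.8]):
            beta = np.array(beta)
            assert cox_partial_loglik(beta, X, time, event) == pytest.approx(
                brute_force_cox_loglik(beta, X, time, event), abs=1e-8
            )

    def test_loglik_with_tied_times(self):
        # Breslow ties: tied events share the full risk-set denominator
        X = np.array([[1.0], [0.5], [-0.2], [0.0]])
        time = np.array([1.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 1, 0])
        beta = np.array([0.7])
        assert cox_partial_loglik(beta, X, time, event) == pytest.approx(
            brute_force_cox_loglik(beta, X, time, event), abs=1e-8
        )

    @pytest.mark.parametrize("seed", [3, 4])
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 6, 3
        X = rng.normal(size=(n, p))
        time = rng.exponential(1.0, n)
        event = np.array([1, 0, 1, 1, 0, 1])
        beta = rng.normal(scale=0.5, size=p)
        grad = cox_partial_gradient(beta, X, time, event)
        eps = 1e-6
        for j in range(p):
            e = np.zeros(p)
            e[j] = eps
            num = (
                brute_force_cox_loglik(beta + e, X, time, event)
                - brute_force_cox_loglik(beta - e, X, time, event)
            ) / (2 * eps)
            assert grad[j] == pytest.approx(num, abs=1e-5)

    def test_breslow_reduces_to_nelson_aalen(self):
        # events at t=1 (3 at risk) and t=2 (2 at risk), censoring at 3
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 1, 0])
        X = np.zeros((3, 1))
        times, cumhaz = breslow_baseline(np.zeros(1), X, time, event)
        assert times.tolist() == [1.0, 2.0]
        assert cumhaz[0] == pytest.approx(1 / 3)
        assert cumhaz[1] == pytest.approx(1 / 3 + 1 / 2)

    def test_mle_matches_lifelines_reference(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(10)
        n, p = 200, 3
        X = rng.normal(size=(n, p))
        beta_true = np.array([0.8, -0.5, 0.0])
        T = rng.exponential(np.exp(-X @ beta_true))
        C = rng.exponential(2.0, n)
        time = np.minimum(T, C) + rng.uniform(0, 1e-9, n)  # break ties
        event = (T <= C).astype(int)
        fit = fit_cox_mle(X, time, event)
        ref = lifelines.CoxPHFitter()
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["time"], df["event"] = time, event
        ref.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-10})
        assert np.abs(
            fit.coef.to_numpy() - ref.params_.to_numpy()
        ).max() < 1e-6


class TestPredictSurvival:
    def _toy_fit(self):
        # 3 subjects, events at t=1,2, censored at 3, beta=0:
        # Lambda0(2) = 1/3 + 1/2
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 1, 0])
        return intercept_only_cox(time, event, columns=["x"])

    def test_survival_at_zero_is_one(self):
        fit = self._toy_fit()
        s = predict_survival(fit, np.zeros((4, 1)), 0.0)
        assert np.all(s == 1.0)

    def test_hand_computed_breslow_survival(self):
        fit = self._toy_fit()
        s = predict_survival(fit, np.zeros((2, 1)), 2.0)
        assert np.allclose(s, np.exp(-(1 / 3 + 1 / 2)))

    def test_zero_coefficients_give_identical_rows(self, rng):
        fit = self._toy_fit()
        s = predict_survival(fit, rng.normal(size=(5, 1)), 2.0)
        assert np.ptp(s) == 0.0

    def test_beyond_last_event_time_flagged(self):
        fit = self._toy_fit()
        s, flag = predict_survival(fit, np.zeros((1, 1)), 10.0, return_flag=True)
        assert flag
        assert s[0] == pytest.approx(np.exp(-(1 / 3 + 1 / 2)))

    def test_non_increasing_in_t(self, rng):
        fit = self._toy_fit()
        x = rng.normal(size=(3, 1))
        values = [
            predict_survival(fit, x, t, return_flag=True)[0]
            for t in (0.0, 0.5, 1.0, 2.0, 3.0)
        ]
        for a, b in zip(values, values[1:]):
            assert np.all(a >= b)


class TestPredictPropensity:
    def test_zero_model_gives_half(self):
        fit = fit_logistic_mle(
            np.zeros((20, 1)) + np.r_[np.ones(10), -np.ones(10)][:, None],
            np.r_[np.ones(10), np.zeros(10)],
        )
        # symmetric design: intercept ~ 0
        assert abs(fit.intercept) < 1e-6

    def test_training_rows_consistent(self, rng):
        X = rng.normal(size=(100, 3))
        y = (rng.random(100) < 0.5).astype(int)
        fit = fit_logistic_mle(X, y)
        again = predict_propensity(fit, X)
        assert np.abs(again - fit.propensities).max() < 1e-12

    def test_monotone_in_positive_coefficient(self, rng):
        X = rng.normal(size=(500, 2))
        y = (rng.random(500) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(int)
        fit = fit_logistic_mle(X, y)
        assert fit.coef.iloc[0] > 0
        x_lo = np.array([[0.0, 0.0]])
        x_hi = np.array([[1.0, 0.0]])
        assert predict_propensity(fit, x_hi) > predict_propensity(fit, x_lo)

    def test_column_mismatch_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = (rng.random(50) < 0.5).astype(int)
        fit = fit_logistic_mle(X, y)
        with pytest.raises(DataError):
            predict_propensity(fit, X.rename(columns={"b": "c"}))


class TestAdaptiveLassoLogistic:
    def test_full_shrinkage_gives_intercept_only(self, rng):
        X = rng.normal(size=(500, 5))
        y = (rng.random(500) < 0.3).astype(int)
        fit = fit_adaptive_lasso_logistic(X, y, alphas=[1e6], seed=0)
        assert (fit.coef == 0).all()
        frac = y.mean()
        assert np.abs(fit.propensities - frac).max() < 1e-6
        assert fit.intercept == pytest.approx(np.log(frac / (1 - frac)), abs=1e-6)

    def test_strong_predictor_selected(self, rng):
        X = rng.normal(size=(2000, 8))
        y = (rng.random(2000) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(int)
        fit = fit_adaptive_lasso_logistic(X, y, seed=1)
        assert fit.coef.iloc[0] != 0

    def test_penalty_free_columns_survive_full_shrinkage(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        y = (rng.random(500) < 1 / (1 + np.exp(-X["a"]))).astype(int)
        fit = fit_adaptive_lasso_logistic(
            X, y, penalty_free=["a"], alphas=[1e6], seed=0
        )
        assert fit.coef["a"] != 0
        assert (fit.coef[list("bcd")] == 0).all()

    def test_row_permutation_invariance_with_ids(self, rng):
        X = rng.normal(size=(400, 6))
        y = (rng.random(400) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        ids = np.arange(400) + 1000
        fit = fit_adaptive_lasso_logistic(X, y, seed=3, patient_id=ids)
        perm = rng.permutation(400)
        fit_p = fit_adaptive_lasso_logistic(
            X[perm], y[perm], seed=3, patient_id=ids[perm]
        )
        assert np.abs(fit.coef.to_numpy() - fit_p.coef.to_numpy()).max() < 1e-8
        assert fit.alpha == pytest.approx(fit_p.alpha, rel=1e-9)

    def test_single_arm_rejected(self, rng):
        with pytest.raises(DataError):
            fit_adaptive_lasso_logistic(rng.normal(size=(50, 2)), np.ones(50))


class TestAdaptiveLassoCox:
    def _survival_data(self, rng, n=600, beta=(1.0, 0, 0, 0)):
        beta = np.asarray(beta, dtype=float)
        X = rng.normal(size=(n, len(beta)))
        T = rng.exponential(np.exp(-X @ beta))
        C = rng.exponential(2.0, n)
        return X, np.minimum(T, C), (T <= C).astype(int)

    def test_signal_kept_noise_dropped(self, rng):
        X, time, event = self._survival_data(rng, n=1500)
        fit = fit_adaptive_lasso_cox(X, time, event, seed=0)
        assert fit.coef.iloc[0] != 0

    def test_no_covariate_limit_equals_nelson_aalen(self, rng):
        X, time, event = self._survival_data(rng, n=200, beta=(0.0,))
        fit = fit_adaptive_lasso_cox(X, time, event, alphas=[1e6], seed=0)
        assert (fit.coef == 0).all()
        na = intercept_only_cox(time, event)
        assert np.allclose(fit.baseline_times, na.baseline_times)
        assert np.allclose(fit.baseline_cumhaz, na.baseline_cumhaz)

    def test_row_permutation_invariance_with_ids(self, rng):
        X, time, event = self._survival_data(rng, n=400, beta=(0.8, 0.0))
        ids = np.arange(400)
        fit = fit_adaptive_lasso_cox(X, time, event, seed=5, patient_id=ids)
        perm = rng.permutation(400)
        fit_p = fit_adaptive_lasso_cox(
            X[perm], time[perm], event[perm], seed=5, patient_id=ids[perm]
        )
        assert np.abs(fit.coef.to_numpy() - fit_p.coef.to_numpy()).max() < 1e-6

    def test_zero_events_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(DataError, match="event"):
            fit_adaptive_lasso_cox(X, np.ones(50), np.zeros(50))

    def test_nonpositive_times_rejected(self, rng):
        X = rng.normal(size=(10, 1))
        with pytest.raises(DataError, match="times"):
            fit_cox_mle(X, np.zeros(10), np.ones(10))

    def test_all_tied_times_warn(self, rng):
        X = rng.normal(size=(30, 1))
        with pytest.warns(UserWarning, match="tied"):
            fit_cox_mle(X, np.ones(30), rng.integers(0, 2, 30) | 1)
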
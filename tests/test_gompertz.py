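"""Gompertz PH likelihood, fitting, life expectancy and family comparison."""

import numpy as np
import pytest
from scipy.integrate import quad

from bmimed.gompertz import (ConvergenceError, GompertzFit, compare_aic,
                             fit_exponential_ph, fit_gompertz_ph,
                             fit_weibull_ph, gompertz_loglik,
                             hazard_ratio_per_sd, predict_life_expectancy,
                             residual_life_gl)
from bmimed.design import DesignSpec, Term
from bmimed.splines import SplineSpec


def quadrature_loglik(gamma, log_b, beta, entry, exit_, event, X):
    """Oracle: per-subject d*log h(t) - int_a^t h(s) ds by adaptive quadrature."""
    total = 0.0
    for i in range(len(entry)):
        lp = log_b + float(X[i] @ beta)
        h = lambda s: np.exp(lp + gamma * s)
        H, _ = quad(h, entry[i], exit_[i], epsabs=1e-13, epsrel=1e-13)
        total += event[i] * np.log(h(exit_[i])) - H
    return total


def simulate_gompertz(rng, n, gamma, log_b, beta, censor_years=4.0,
                      entry_range=(51.0, 90.0)):
    entry = rng.uniform(*entry_range, n)
    X = rng.normal(size=(n, np.size(beta)))
    lp = log_b + X @ np.atleast_1d(beta)
    u = rng.random(n)
    death = np.log(np.exp(gamma * entry) + gamma * (-np.log(u)) * np.exp(-lp)) / gamma
    exit_ = np.minimum(death, entry + censor_years)
    event = (death <= entry + censor_years).astype(float)
    return entry, exit_, event, X


def make_fit(gamma, log_b, beta=(), names=None, design_spec=None):
    beta = np.asarray(beta, dtype=float)
    k = 2 + beta.size
    return GompertzFit(gamma=gamma, log_b=log_b, beta=beta,
                       names=list(names or [f"x{i}" for i in range(beta.size)]),
                       vcov=np.eye(k), loglik=0.0, aic=0.0, n=0, n_events=1,
                       converged=True, grad_norm=0.0, design_spec=design_spec)


class TestLoglik:
    def test_matches_quadrature_oracle(self, rng):
        n = 20
        entry = rng.uniform(51, 90, n)
        exit_ = entry + rng.uniform(0.1, 4.5, n)
        event = rng.integers(0, 2, n).astype(float)
        X = rng.normal(size=(n, 3))
        beta = np.array([0.3, -0.2, 0.1])
        ll = gompertz_loglik(0.09, -9.0, beta, entry, exit_, event, X=X)
        oracle = quadrature_loglik(0.09, -9.0, beta, entry, exit_, event, X)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_exponential_limit_no_truncation(self, rng):
        """gamma -> 0, no covariates, entry 0: d log(lam) - lam * sum(t)."""
        n = 15
        exit_ = rng.uniform(0.5, 10.0, n)
        event = rng.integers(0, 2, n).astype(float)
        lam = 0.07
        ll = gompertz_loglik(0.0, np.log(lam), None, np.full(n, 1e-9), exit_, event)
        expected = event.sum() * np.log(lam) - lam * exit_.sum()
        assert ll == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_weights_scale_linearly(self, rng):
        n = 10
        entry = rng.uniform(51, 80, n)
        exit_ = entry + rng.uniform(0.5, 4, n)
        event = rng.integers(0, 2, n).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        one = gompertz_loglik(0.08, -9.5, None, entry, exit_, event, weights=w)
        two = gompertz_loglik(0.08, -9.5, None, entry, exit_, event, weights=2 * w)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_exit_before_entry_rejected(self):
        with pytest.raises(ValueError):
            gompertz_loglik(0.08, -9.0, None, [70.0], [69.0], [1.0])


class TestFit:
    def test_simulation_recovery_within_3se(self, rng):
        truth = dict(gamma=0.09, log_b=-9.0, beta=0.4)
        entry, exit_, event, X = simulate_gompertz(
            rng, 5000, truth["gamma"], truth["log_b"], truth["beta"])
        fit = fit_gompertz_ph(entry, exit_, event, X=X, names=["x"])
        se = np.sqrt(np.diag(fit.vcov))
        assert abs(fit.gamma - truth["gamma"]) < 3 * se[0]
        assert abs(fit.log_b - truth["log_b"]) < 3 * se[1]
        assert abs(fit.beta[0] - truth["beta"]) < 3 * se[2]
        assert fit.grad_norm < 1e-6
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik)

    def test_null_coefficient_wald_z_in_range(self, rng):
        entry, exit_, event, X = simulate_gompertz(rng, 3000, 0.09, -9.0, 0.0)
        fit = fit_gompertz_ph(entry, exit_, event, X=X, names=["x"])
        z = fit.beta[0] / np.sqrt(fit.vcov[2, 2])
        assert abs(z) < 3

    def test_matches_dense_grid_search(self, rng):
        """n=30 no-covariate MLE vs a 2-D grid over (gamma, log_b)."""
        entry, exit_, event, _ = simulate_gompertz(rng, 30, 0.10, -9.0, ())
        fit = fit_gompertz_ph(entry, exit_, event)
        gammas = np.linspace(0.01, 0.35, 171)
        log_bs = np.linspace(-28.0, -4.0, 481)
        best, argbest = -np.inf, None
        for g in gammas:
            for lb in log_bs:
                ll = gompertz_loglik(g, lb, None, entry, exit_, event)
                if ll > best:
                    best, argbest = ll, (g, lb)
        assert abs(fit.gamma - argbest[0]) <= gammas[1] - gammas[0]
        assert abs(fit.log_b - argbest[1]) <= log_bs[1] - log_bs[0]
        assert fit.loglik >= best - 1e-6

    def test_no_events_rejected(self, rng):
        entry = rng.uniform(51, 80, 50)
        with pytest.raises(ValueError, match="events"):
            fit_gompertz_ph(entry, entry + 1.0, np.zeros(50))

    def test_collinear_design_names_columns(self, rng):
        entry, exit_, event, X = simulate_gompertz(rng, 200, 0.1, -9.0, 0.2)
        X2 = np.column_stack([X, 2 * X[:, 0]])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_gompertz_ph(entry, exit_, event, X=X2, names=["x", "dup"])

    def test_profile_likelihood_peaks_at_mle(self, rng):
        entry, exit_, event, X = simulate_gompertz(rng, 800, 0.09, -9.0, 0.3)
        fit = fit_gompertz_ph(entry, exit_, event, X=X)
        at_mle = gompertz_loglik(fit.gamma, fit.log_b, fit.beta, entry, exit_,
                                 event, X=X)
        for _ in range(20):
            pert = rng.normal(0, 0.02, 3)
            ll = gompertz_loglik(fit.gamma + pert[0], fit.log_b + pert[1],
                                 fit.beta + pert[2], entry, exit_, event, X=X)
            assert ll <= at_mle + 1e-9


class TestLifeExpectancy:
    def test_exponential_closed_form(self):
        fit = make_fit(0.0, np.log(0.1))
        assert predict_life_expectancy(fit, np.zeros(0), 70.0) == pytest.approx(80.0, abs=1e-7)

    def test_matches_trapezoid_integration(self, rng):
        fit = make_fit(0.095, -10.2, beta=[0.3])
        x = np.array([1.2])
        entry = 72.0
        got = predict_life_expectancy(fit, x, entry)
        t = np.linspace(entry, 130.0, 240_001)
        lp = fit.log_b + x @ fit.beta
        surv = np.exp(-np.exp(lp) * (np.exp(fit.gamma * t) - np.exp(fit.gamma * entry)) / fit.gamma)
        oracle = entry + np.trapezoid(surv, t)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_null_covariate_does_not_move_life_expectancy(self):
        fit = make_fit(0.09, -10.0, beta=[0.2, 0.0])
        a = predict_life_expectancy(fit, np.array([1.0, 5.0]), 70.0)
        b = predict_life_expectancy(fit, np.array([1.0, -5.0]), 70.0)
        assert a == pytest.approx(b, abs=1e-10)

    def test_positive_coefficient_lowers_life_expectancy(self):
        fit = make_fit(0.09, -10.0, beta=[0.4])
        hi = predict_life_expectancy(fit, np.array([1.0]), 70.0)
        lo = predict_life_expectancy(fit, np.array([0.0]), 70.0)
        assert hi < lo

    def test_exponential_limit_matches_exact_formula(self):
        lam = 0.05
        fit = make_fit(1e-10, np.log(lam))
        got = predict_life_expectancy(fit, np.zeros(0), 60.0)
        assert got == pytest.approx(60.0 + 1 / lam, abs=1e-6)

    def test_survival_curve_shape(self):
        """Conditional survival starts at 1, decreases, and hits ~0 by 130."""
        gamma, lp, entry = 0.09, -10.0 + 0.09 * 0, 65.0
        t = np.linspace(entry, 130.0, 500)
        surv = np.exp(-np.exp(lp) * (np.exp(gamma * t) - np.exp(gamma * entry)) / gamma)
        assert surv[0] == pytest.approx(1.0)
        assert np.all(np.diff(surv) <= 0)
        assert surv[-1] < 1e-8

    def test_entry_outside_support_rejected(self):
        fit = make_fit(0.09, -10.0)
        with pytest.raises(ValueError):
            predict_life_expectancy(fit, np.zeros(0), 20.0)

    def test_vectorised_quadrature_agrees_with_adaptive(self, rng):
        fit = make_fit(0.085, -10.5, beta=[0.25])
        entries = np.array([55.0, 70.0, 85.0])
        lp = np.full(3, fit.log_b + 0.25 * 0.7)
        fast = residual_life_gl(fit.gamma, lp, entries)
        for i, a in enumerate(entries):
            slow = predict_life_expectancy(fit, np.array([0.7]), a) - a
            assert fast[i] == pytest.approx(slow, abs=1e-6)


class TestHazardRatio:
    def test_null_coefficient_gives_unit_hr(self):
        fit = make_fit(0.09, -10.0, beta=[0.0], names=["eaa"])
        assert hazard_ratio_per_sd(fit, "eaa", 5.3)["hr"] == pytest.approx(1.0)

    def test_closed_form(self):
        fit = make_fit(0.09, -10.0, beta=[0.1], names=["eaa"])
        hr = hazard_ratio_per_sd(fit, "eaa", 5.3)
        assert hr["hr"] == pytest.approx(np.exp(0.53))
        assert hr["ci_low"] < hr["hr"] < hr["ci_high"]

    def test_negative_coefficient_gives_protective_hr(self):
        fit = make_fit(0.09, -10.0, beta=[-0.2], names=["eaa"])
        assert hazard_ratio_per_sd(fit, "eaa", 1.0)["hr"] < 1.0

    def test_splined_variable_rejected(self):
        spec = DesignSpec(terms=(Term("bmi", "spline",
                                      SplineSpec(knots=(20.0, 27.0, 35.0))),))
        fit = make_fit(0.09, -10.0, beta=[0.1, 0.2], names=["bmi", "bmi'"],
                       design_spec=spec)
        with pytest.raises(ValueError, match="spline"):
            hazard_ratio_per_sd(fit, "bmi", 6.1)


class TestFamilyComparison:
    def test_gompertz_data_prefers_gompertz(self, rng):
        entry, exit_, event, _ = simulate_gompertz(rng, 5000, 0.10, -9.2, ())
        tab = compare_aic(entry, exit_, event)
        assert tab.loc[0, "family"] == "gompertz"
        assert tab["converged"].all()

    def test_constant_hazard_prefers_exponential(self, rng):
        n = 4000
        entry = rng.uniform(51, 90, n)
        death = entry + rng.exponential(1 / 0.08, n)
        exit_ = np.minimum(death, entry + 4.0)
        event = (death <= entry + 4.0).astype(float)
        tab = compare_aic(entry, exit_, event).set_index("family")
        # one wasted parameter, essentially no log-likelihood gain
        assert tab.loc["exponential", "aic"] < tab.loc["gompertz", "aic"]
        gain = tab.loc["gompertz", "loglik"] - tab.loc["exponential", "loglik"]
        assert 0 <= gain < 4.0

    def test_weibull_reduces_to_exponential_at_unit_shape(self, rng):
        entry, exit_, event, _ = simulate_gompertz(rng, 1000, 0.09, -9.5, ())
        fe = fit_exponential_ph(entry, exit_, event)
        fw = fit_weibull_ph(entry, exit_, event)
        assert fw.loglik >= fe.loglik - 1e-6  # nested model

    def test_vcov_is_symmetric_psd(self, rng):
        entry, exit_, event, X = simulate_gompertz(rng, 2000, 0.09, -9.0, 0.3)
        fit = fit_gompertz_ph(entry, exit_, event, X=X)
        np.testing.assert_allclose(fit.vcov, fit.vcov.T)
        assert np.linalg.eigvalsh(fit.vcov).min() > -1e-12
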
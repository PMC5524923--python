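"""Likelihood, anchor-time profiling and maximum-likelihood fitting."""

import math

import numpy as np
import pytest
from scipy import stats

from devilgrowth import (
    AnchorConvention,
    FitConfig,
    TumourSeries,
    fit_model,
    get_model,
    log_likelihood,
    model_solution,
    profile_epsilon,
    profile_t0,
    time_to_volume,
)
from devilgrowth.growth_models import EPSILON_FLOOR
from devilgrowth.likelihood import Measurement

from conftest import make_series

LOG_2PI = math.log(2.0 * math.pi)


class TestSeriesValidation:
    def test_measurement_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            Measurement(t=0.0, V=0.0)

    @pytest.mark.parametrize(
        "t, V",
        [
            ([10.0, 20.0], [1.0, 2.0]),  # first time not zero
            ([0.0, 0.0], [1.0, 2.0]),  # duplicate times
            ([0.0, 50.0], [1.0, -2.0]),  # negative volume
            ([], []),  # empty
        ],
    )
    def test_series_invariants(self, t, V):
        with pytest.raises(ValueError):
            TumourSeries("t1", "h1", np.array(t), np.array(V))


class TestLogLikelihood:
    def test_single_point_on_curve_unit_variance(self):
        """Zero residual with epsilon = 1: the standard-normal log-density
        at 0, -log(2 pi)/2."""
        s = make_series("exponential", [0.02], t0=-100.0, times=[0.0])
        ll = log_likelihood([s], get_model("exponential"), [0.02], [-100.0], 1.0)
        assert ll == pytest.approx(-0.5 * LOG_2PI, rel=1e-12)

    def test_two_known_residuals(self):
        """Log-residuals {+0.1, -0.1} at epsilon = 0.01 plug straight into
        the normal log-density."""
        s = make_series(
            "exponential", [0.02], t0=-100.0, times=[0.0, 90.0], noise=[0.1, -0.1]
        )
        ll = log_likelihood([s], get_model("exponential"), [0.02], [-100.0], 0.01)
        expected = 2 * (-0.5 * math.log(2 * math.pi * 0.01)) - 1.0
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_matches_scalar_normal_density_sum(self):
        """Brute-force oracle: sum scipy normal log-densities point by
        point over a random cohort and random anchors."""
        rng = np.random.default_rng(3)
        spec = get_model("logistic")
        theta = [0.02, 200.0]
        cohort, t0s = [], []
        for i in range(6):
            t0 = rng.uniform(-300, 0)
            times = np.sort(np.concatenate([[0.0], rng.uniform(30, 400, size=2)]))
            noise = rng.normal(0, 0.2, size=3)
            cohort.append(
                make_series("logistic", theta, t0, times, tumour_id=f"t{i}", noise=noise)
            )
            t0s.append(t0 + rng.uniform(-20, 20))  # anchors off-optimum on purpose
        eps = 0.05
        anchor = AnchorConvention()
        expected = 0.0
        for s, t0 in zip(cohort, t0s):
            mu = np.log(
                model_solution(spec, theta, AnchorConvention(t0=t0), s.t)
            )
            expected += stats.norm.logpdf(np.log(s.V), mu, math.sqrt(eps)).sum()
        got = log_likelihood(cohort, spec, theta, t0s, eps)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_invalid_anchor_gives_minus_inf(self):
        """An anchor pushing observations outside the Mendelsohn domain is a
        rejected point, not an exception."""
        s = make_series("exponential", [0.02], -100.0, [0.0, 90.0])
        ll = log_likelihood([s], get_model("mendelsohn"), [0.02, 0.5], [3000.0], 0.05)
        assert ll == -np.inf


class TestProfileT0:
    def test_exponential_closed_form_exact_recovery(self):
        """Noise-free exponential series: the closed form
        t0 = mean_j[t_j - (log V_j - log V0)/r] recovers the truth."""
        t0_true = -212.5
        s = make_series("exponential", [0.02], t0_true, [0.0, 95.0, 200.0])
        t0_hat, ss = profile_t0(s, get_model("exponential"), [0.02])
        assert t0_hat == pytest.approx(t0_true, abs=1e-9)
        assert ss == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("name, theta, V1", [
        ("logistic", [0.016, 364.0], 42.0),
        ("gompertz", [0.05, 0.01], 3.3),
        ("von_bertalanffy", [0.3, 0.05], 17.0),
    ])
    def test_singleton_solved_by_inversion(self, name, theta, V1):
        """One measurement: zero residual, t0 from inverting the curve
        through the point."""
        spec = get_model(name)
        s = TumourSeries("t1", "h1", np.array([0.0]), np.array([V1]))
        t0_hat, ss = profile_t0(s, spec, theta)
        assert ss == 0.0
        assert t0_hat == pytest.approx(
            -time_to_volume(spec, theta, AnchorConvention(), V1), rel=1e-9
        )

    def test_logistic_noisy_matches_dense_grid_oracle(self):
        """3-point noisy logistic series vs an independent dense grid search
        over t0 in [-2000, 2000] at 0.01-day resolution."""
        spec = get_model("logistic")
        theta = np.array([0.016, 364.0])
        s = make_series(
            "logistic", theta, -150.0, [0.0, 90.0, 180.0], noise=[0.15, -0.2, 0.1]
        )
        t0_hat, ss = profile_t0(s, spec, theta)

        grid = np.arange(-2000.0, 2000.0, 0.01)
        pred = 364.0 / (
            1.0 + (364.0 / 0.125 - 1.0)
            * np.exp(-0.016 * (s.t[:, None] - grid[None, :]))
        )
        ss_grid = ((np.log(s.V)[:, None] - np.log(pred)) ** 2).sum(axis=0)
        j = np.argmin(ss_grid)
        assert t0_hat == pytest.approx(grid[j], abs=0.1)
        assert ss <= ss_grid[j] + 1e-10


class TestProfileEpsilon:
    def test_mean_squared_residual(self):
        assert profile_epsilon([0.1, -0.1]) == pytest.approx(0.01, rel=1e-12)

    def test_perfect_fit_floored(self):
        assert profile_epsilon([0.0, 0.0, 0.0]) == EPSILON_FLOOR

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            profile_epsilon([])

    def test_consistency_on_simulated_residuals(self):
        rng = np.random.default_rng(11)
        res = rng.normal(0.0, 0.2, size=1000)  # variance 0.04
        assert profile_epsilon(res) == pytest.approx(0.04, rel=0.15)


class TestFitModel:
    def test_exact_exponential_data_recovered(self, exact_exponential_cohort):
        """Noise-free cohort: r recovered to 1e-6 and the likelihood sits at
        the epsilon-floor ceiling (perfect fit)."""
        fit = fit_model(
            exact_exponential_cohort,
            get_model("exponential"),
            FitConfig(multistart=6, seed=0),
        )
        assert fit.theta_hat[0] == pytest.approx(0.02, abs=1e-6)
        assert fit.epsilon_hat == EPSILON_FLOOR
        n = fit.n_obs
        ll_ceiling = -0.5 * n * (LOG_2PI + math.log(EPSILON_FLOOR))
        assert fit.loglik == pytest.approx(ll_ceiling, rel=1e-6)

    def test_exponential_equals_fixed_effects_regression(self, noisy_logistic_cohort):
        """Analytic oracle: exponential growth with lognormal error is a
        linear fixed-effects model in log space — the MLE of r equals the
        pooled within-tumour least-squares slope (via statsmodels OLS with
        per-tumour intercepts)."""
        import statsmodels.api as sm
        import pandas as pd

        series_set, _ = noisy_logistic_cohort
        fit = fit_model(series_set, get_model("exponential"), FitConfig(multistart=6, seed=0))

        rows = [
            {"y": math.log(v), "t": t, "tum": s.tumour_id}
            for s in series_set
            for t, v in zip(s.t, s.V)
        ]
        df = pd.DataFrame(rows)
        X = pd.get_dummies(df["tum"], dtype=float)
        X["t"] = df["t"]
        ols = sm.OLS(df["y"], X).fit()
        assert fit.theta_hat[0] == pytest.approx(ols.params["t"], abs=1e-6)

    def test_insufficient_data_raises(self):
        s = make_series("exponential", [0.02], -50.0, [0.0, 90.0])
        with pytest.raises(ValueError, match="AICc"):
            fit_model([s], get_model("logistic"), FitConfig(multistart=2))

    def test_deterministic_given_seed(self, noisy_logistic_cohort):
        series_set, _ = noisy_logistic_cohort
        cfg = FitConfig(multistart=3, seed=5)
        f1 = fit_model(series_set, get_model("logistic"), cfg)
        f2 = fit_model(series_set, get_model("logistic"), cfg)
        np.testing.assert_array_equal(f1.theta_hat, f2.theta_hat)
        assert f1.loglik == f2.loglik

    def test_min_points_filter_drops_singletons(self, noisy_logistic_cohort):
        series_set, _ = noisy_logistic_cohort
        cfg = FitConfig(multistart=3, seed=0, min_points_per_tumour=2)
        fit = fit_model(series_set, get_model("exponential"), cfg)
        expected_n = sum(s.n_obs for s in series_set if s.n_obs >= 2)
        assert fit.n_obs == expected_n


class TestInvariances:
    def test_v0_shift_leaves_loglik_unchanged(self, noisy_logistic_cohort):
        """Changing the anchor volume from 0.125 to 100 cm^3 shifts every
        anchor time by one model-dependent constant and the maximised
        log-likelihood by < 1e-6."""
        series_set, _ = noisy_logistic_cohort
        f_small = fit_model(
            series_set, get_model("logistic"), FitConfig(multistart=4, seed=0, V0=0.125)
        )
        f_big = fit_model(
            series_set, get_model("logistic"), FitConfig(multistart=4, seed=0, V0=100.0)
        )
        assert abs(f_small.loglik - f_big.loglik) < 1e-6
        shifts = np.array(
            [f_big.t0_hat[k] - f_small.t0_hat[k] for k in f_small.t0_hat]
        )
        assert shifts.std() < 1e-3
        assert abs(shifts.mean()) > 100.0  # the shift itself is large

    def test_time_translation_shifts_t0_only(self):
        """Observing the same tumour 55 days later (a constant added to its
        absolute observation times) shifts the fitted anchor by exactly -55
        days and leaves the profile residual unchanged."""
        spec = get_model("logistic")
        theta = [0.016, 364.0]
        noise = [0.05, -0.1, 0.08]
        base = make_series("logistic", theta, -120.0, [0.0, 90.0, 200.0], noise=noise)
        shifted = make_series("logistic", theta, -120.0, [0.0, 90.0, 200.0], noise=noise)
        shifted.t = shifted.t + 55.0  # same volumes on a translated clock
        t0_base, ss_base = profile_t0(base, spec, theta)
        t0_shift, ss_shift = profile_t0(shifted, spec, theta)
        assert ss_shift == pytest.approx(ss_base, abs=1e-10)
        assert t0_shift == pytest.approx(t0_base + 55.0, abs=1e-3)

    def test_optimum_beats_truth(self, noisy_logistic_cohort):
        """The maximised likelihood dominates the likelihood at the true
        generating parameters."""
        series_set, truth = noisy_logistic_cohort
        spec = get_model("logistic")
        fit = fit_model(series_set, spec, FitConfig(multistart=4, seed=0))
        theta_true = np.array(truth.theta_of_group["diploid"])
        t0s = []
        ss = 0.0
        for s in series_set:
            t0_i, ss_i = profile_t0(s, spec, theta_true)
            t0s.append(t0_i)
            ss += ss_i
        eps_true = max(ss / fit.n_obs, EPSILON_FLOOR)
        ll_truth = log_likelihood(series_set, spec, theta_true, t0s, eps_true)
        assert fit.loglik >= ll_truth - 1e-6

    def test_noise_free_fit_has_no_residual_trend(self):
        """Monotone noise-free logistic input: fitted residuals carry no
        systematic sign (they are ~0)."""
        theta = [0.016, 364.0]
        cohort = [
            make_series("logistic", theta, t0, [0.0, 90.0, 180.0], tumour_id=f"t{i}")
            for i, t0 in enumerate([-250.0, -120.0, 0.0, 60.0])
        ]
        fit = fit_model(cohort, get_model("logistic"), FitConfig(multistart=6, seed=1))
        anchor = AnchorConvention()
        for s in cohort:
            pred = model_solution(
                fit.spec, fit.theta_hat,
                AnchorConvention(t0=fit.t0_hat[s.tumour_id]), s.t,
            )
            res = np.log(s.V) - np.log(pred)
            assert np.max(np.abs(res)) < 1e-3
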
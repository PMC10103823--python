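"""Model-selection gate and two-segment breakpoint detection."""

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.stats import norm

from droughtthresh.coincidence import ResponseCurve
from droughtthresh.threshold_detection import (
    FLAG_LINEAR,
    FLAG_LOW_R,
    FLAG_POOR_EXP,
    FLAG_SLOPE_ORDER,
    detect_threshold,
    fit_exponential,
    fit_linear,
    gate_nonlinearity,
    segmented_fit,
)

QS = np.arange(1, 51)
THETA = norm.ppf(QS / 100.0)  # Gaussian percentile anomalies, [-2.33, 0]


def make_curve(r, theta=THETA, qs=QS):
    r = np.asarray(r, dtype=float)
    return ResponseCurve(q=qs, theta=theta, r=r, n_drought=np.full(len(qs), 100),
                         veg_threshold=-1.0, pooled_n=900)


def piecewise(theta, break_q=15, slope_a=-0.05, slope_b=-0.40, level=0.2):
    """Two-segment response: mild slope above the break, steep below."""
    tb = THETA[break_q - 1]
    below = theta < tb
    return level + slope_a * (theta - tb) + (slope_b - slope_a) * np.where(below, theta - tb, 0.0)


def exponential_r(theta, m=0.02, beta=-1.4, k=0.08):
    return m * np.exp(beta * theta) + k


class TestLinearFit:
    def test_noiseless_line_recovered(self):
        fit = fit_linear(make_curve(0.1 - 0.2 * THETA))
        assert fit.slope == pytest.approx(-0.2, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_r(self):
        fit = fit_linear(make_curve(np.full(50, 0.3)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        r = 0.2 - 0.1 * THETA + rng.normal(0, 0.02, 50)
        fit = fit_linear(make_curve(r))
        X = np.column_stack([np.ones(50), THETA])
        beta = np.linalg.solve(X.T @ X, X.T @ r)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_theta_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(make_curve(np.full(50, 0.1), theta=np.zeros(50)))


class TestExponentialFit:
    def test_noiseless_parameters_recovered(self):
        # spec'd parameter point, verified against scipy.curve_fit independently
        theta = np.linspace(-2.0, 0.0, 50)
        r = 0.2 * np.exp(-3.0 * theta) + 0.1
        fit = fit_exponential(make_curve(r, theta=theta))
        assert fit.m == pytest.approx(0.2, abs=1e-4)
        assert fit.beta == pytest.approx(-3.0, abs=1e-4)
        assert fit.k == pytest.approx(0.1, abs=1e-4)
        popt, _ = curve_fit(lambda t, m, b, k: m * np.exp(b * t) + k, theta, r,
                            p0=[0.1, -2.0, 0.0], maxfev=10_000)
        np.testing.assert_allclose([fit.m, fit.beta, fit.k], popt, atol=1e-4)

    def test_constant_r_explained_without_structure(self):
        fit = fit_exponential(make_curve(np.full(50, 0.25)))
        lin = fit_linear(make_curve(np.full(50, 0.25)))
        assert fit.rss <= lin.rss + 1e-12
        np.testing.assert_allclose(fit.predict(THETA), 0.25, atol=1e-8)
        assert fit.adj_r2 <= 0.0

    def test_nests_linear_in_small_beta_limit(self):
        r = 0.3 - 0.08 * THETA
        fit = fit_exponential(make_curve(r))
        lin = fit_linear(make_curve(r))
        assert fit.rss <= lin.rss + 1e-6

    def test_noisy_exponential_close_to_curve_fit(self):
        rng = np.random.default_rng(1)
        r = exponential_r(THETA) + rng.normal(0, 0.01, 50)
        fit = fit_exponential(make_curve(r))
        popt, _ = curve_fit(lambda t, m, b, k: m * np.exp(b * t) + k, THETA, r,
                            p0=[0.02, -1.4, 0.08], maxfev=10_000)
        resid_ours = fit.rss
        resid_ref = float(np.sum((popt[0] * np.exp(popt[1] * THETA) + popt[2] - r) ** 2))
        assert resid_ours <= resid_ref + 1e-10


class TestGate:
    def test_noiseless_linear_flagged_linear(self):
        curve = make_curve(0.1 - 0.2 * THETA)
        decision = gate_nonlinearity(fit_linear(curve), fit_exponential(curve))
        assert decision == FLAG_LINEAR

    def test_poor_exp_fit_excluded_regardless_of_aic(self):
        rng = np.random.default_rng(2)
        curve = make_curve(0.1 + rng.normal(0, 0.05, 50))  # pure noise
        lin = fit_linear(curve)
        exp = fit_exponential(curve)
        exp.adj_r2 = 0.4
        exp.aic = lin.aic - 100.0
        assert gate_nonlinearity(lin, exp) == FLAG_POOR_EXP

    def test_exponential_curve_accepted(self):
        curve = make_curve(exponential_r(THETA))
        assert gate_nonlinearity(fit_linear(curve), fit_exponential(curve)) == "nonlinear"

    def test_selection_rates_under_noise(self):
        # AIC + R^2 gate distinguishes linear from exponential generators at
        # noise sd 0.02 in nearly every seeded rep
        rng = np.random.default_rng(3)
        n_lin = n_exp = 0
        reps = 100
        for _ in range(reps):
            lin_curve = make_curve(0.55 + 0.2 * THETA + rng.normal(0, 0.02, 50))
            c = make_curve(exponential_r(THETA) + rng.normal(0, 0.02, 50))
            if gate_nonlinearity(fit_linear(lin_curve), fit_exponential(lin_curve)) != "nonlinear":
                n_lin += 1
            if gate_nonlinearity(fit_linear(c), fit_exponential(c)) == "nonlinear":
                n_exp += 1
        assert n_lin >= 0.95 * reps
        assert n_exp >= 0.95 * reps


class TestSegmentedFit:
    def test_noiseless_breakpoint_exact(self):
        seg = segmented_fit(make_curve(piecewise(THETA)))
        assert seg.break_q == 15
        assert seg.beta2 == pytest.approx(-0.35, abs=1e-8)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            r = piecewise(THETA, break_q=int(rng.integers(8, 40))) + rng.normal(0, 0.03, 50)
            seg = segmented_fit(make_curve(r))
            # independent exhaustive search with statsmodels-free normal equations
            best_sse, best_q = np.inf, None
            for i in range(50):
                tc = THETA[i]
                below = THETA < tc
                if below.sum() < 3 or (~below).sum() < 3:
                    continue
                X = np.column_stack([np.ones(50), THETA, np.where(below, THETA - tc, 0.0)])
                coef = np.linalg.solve(X.T @ X, X.T @ r)
                sse = float(np.sum((r - X @ coef) ** 2))
                if sse < best_sse - 1e-15:
                    best_sse, best_q = sse, QS[i]
            assert seg.break_q == best_q
            assert seg.sse == pytest.approx(best_sse, abs=1e-9)

    def test_pure_linear_beta2_negligible(self):
        seg = segmented_fit(make_curve(0.3 - 0.1 * THETA))
        assert abs(seg.beta2) < 1e-6

    def test_predicted_curve_continuous_at_break(self):
        rng = np.random.default_rng(5)
        seg = segmented_fit(make_curve(piecewise(THETA) + rng.normal(0, 0.02, 50)))
        eps = 1e-9
        left = seg.predict(np.array([seg.break_theta - eps]))
        right = seg.predict(np.array([seg.break_theta + eps]))
        assert left[0] == pytest.approx(right[0], abs=1e-6)

    def test_min_points_respected(self):
        seg = segmented_fit(make_curve(piecewise(THETA)), min_seg_points=3)
        below = np.sum(THETA < seg.break_theta)
        assert below >= 3 and 50 - below >= 3

    def test_too_few_samples_returns_none(self):
        c = make_curve(piecewise(THETA))
        c.r[:-4] = np.nan
        assert segmented_fit(c) is None


class TestDetectThreshold:
    def test_recovery_under_rate_noise(self):
        # noisy two-phase curves (r-noise sd 0.03): threshold within +/-2 of
        # the true inflection in at least 90% of seeded reps
        hits = 0
        valid = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            r = piecewise(THETA, break_q=15) + rng.normal(0, 0.03, 50)
            res = detect_threshold(make_curve(r))
            if res.valid:
                valid += 1
                hits += abs(res.T - 15) <= 2
        assert hits >= 0.90 * reps
        assert valid >= 0.95 * reps

    def test_low_coincidence_flagged_but_reported(self):
        r = piecewise(THETA, slope_a=-0.02, slope_b=-0.10, level=0.05)
        res = detect_threshold(make_curve(r))
        assert res.max_r < 0.3
        if res.valid:
            assert FLAG_LOW_R in res.flags
            assert res.T is not None

    def test_positive_beta2_is_slope_order_violation(self):
        # steepening above the break (concave curve) must be excluded
        r = piecewise(THETA, slope_a=-0.40, slope_b=-0.05, level=0.35)
        res = detect_threshold(make_curve(r))
        assert not res.valid
        assert res.flags & {FLAG_SLOPE_ORDER, FLAG_LINEAR, FLAG_POOR_EXP}

    def test_generator_cluster_recovery(self):
        # full pooled clusters from the synthetic generator, defaults
        from tests.conftest import cluster_curve

        hits = valid = 0
        reps = 30
        for seed in range(reps):
            res = detect_threshold(cluster_curve(seed))
            if res.valid:
                valid += 1
                hits += abs(res.T - 15) <= 3
        assert valid >= 0.9 * reps
        assert hits >= 0.7 * valid

    def test_exactly_one_terminal_status(self):
        rng = np.random.default_rng(6)
        terminal = {FLAG_LINEAR, FLAG_POOR_EXP, FLAG_SLOPE_ORDER, "unestimable", "valid"}
        for _ in range(30):
            r = np.clip(piecewise(THETA) + rng.normal(0, rng.uniform(0.01, 0.2), 50), 0, 1)
            res = detect_threshold(make_curve(r))
            assert len(res.flags & terminal) == 1
            assert (res.T is not None) == res.valid

    def test_identifiability_monotone_in_contrast(self):
        # a stronger Phase-B slope never worsens median recovery error
        errs = []
        for slope_b in (-0.2, -0.4, -0.6):
            err = []
            for seed in range(40):
                rng = np.random.default_rng(seed)
                r = piecewise(THETA, slope_b=slope_b) + rng.normal(0, 0.03, 50)
                res = detect_threshold(make_curve(r))
                if res.valid:
                    err.append(abs(res.T - 15))
            errs.append(np.median(err))
        assert errs[2] <= errs[0] + 1e-9
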
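"""Polynomial screening, Davies testing, and broken-line estimation."""

import numpy as np
import pytest
from scipy import stats

from dogaging.config import OldCurveSpec, TrajectorySpec
from dogaging.segmented import (
    breakpoint_confint,
    compare_breakpoints,
    davies_test,
    fit_age_polynomials,
    fit_segmented,
    screen_trait,
    segment_slopes,
    select_breakpoints,
)


def _grid_rss(x, y, step=0.01):
    best = np.inf
    for psi in np.arange(x.min() + 0.3, x.max() - 0.3, step):
        X = np.column_stack([np.ones_like(x), x, np.maximum(0, x - psi)])
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        best = min(best, float(((y - X @ b) ** 2).sum()))
    return best


class TestPolynomials:
    def test_exact_linear(self):
        x = np.linspace(1, 20, 50)
        rep = fit_age_polynomials(x, 2 * x)
        assert rep.r2[1] == pytest.approx(1.0)

    def test_noiseless_quadratic(self):
        x = np.linspace(1, 20, 50)
        rep = fit_age_polynomials(x, 1 + x - 0.1 * x**2)
        assert rep.r2[2] == pytest.approx(1.0) and rep.r2[3] == pytest.approx(1.0)
        assert rep.r2[1] < 1.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 20, 200)
        y = rng.normal(size=200)
        rep = fit_age_polynomials(x, y)
        for d in (1, 2, 3):
            X = np.vander(x, d + 1, increasing=True)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            rss = ((y - X @ beta) ** 2).sum()
            r2 = 1 - rss / ((y - y.mean()) ** 2).sum()
            assert rep.r2[d] == pytest.approx(r2, abs=1e-10)

    def test_r2_monotone_in_degree(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.uniform(0, 10, 100)
            y = rng.normal(size=100)
            rep = fit_age_polynomials(x, y)
            assert rep.r2[1] <= rep.r2[2] + 1e-12 <= rep.r2[3] + 2e-12

    def test_constant_response_flagged(self):
        rep = fit_age_polynomials(np.linspace(1, 5, 10), np.full(10, 3.0))
        assert rep.constant_response and rep.max_r2 == 0.0


class TestScreening:
    def test_weak_association_dropped(self):
        rep = fit_age_polynomials(np.linspace(1, 20, 100),
                                  np.random.default_rng(2).normal(size=100))
        rep.r2 = {1: 0.02, 2: 0.025, 3: 0.028}
        assert screen_trait(rep) == "drop"

    def test_clear_association_kept(self):
        rep = fit_age_polynomials(np.linspace(1, 20, 100), np.linspace(1, 20, 100))
        assert screen_trait(rep) == "keep"

    def test_boundary_is_strict(self):
        rep = fit_age_polynomials(np.linspace(1, 5, 10), np.linspace(1, 5, 10))
        rep.r2 = {1: 0.1, 2: 0.1, 3: 0.1}
        assert screen_trait(rep) == "keep"


class TestDaviesTest:
    def test_single_candidate_reduces_to_plain_p(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 20, 300)
        y = 1 - 0.1 * x + 0.3 * np.maximum(0, x - 8) + rng.normal(0, 1, 300)
        p = davies_test(x, y, k=1)
        psi = np.quantile(x, 0.05)
        X = np.column_stack([np.ones_like(x), x, np.maximum(0, x - psi)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = (resid @ resid) / (len(x) - 3)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t = beta[-1] / np.sqrt(cov[-1, -1])
        assert p == pytest.approx(2 * stats.norm.sf(abs(t)), abs=1e-12)

    def test_strong_kink_detected(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 20, 200)
        y = np.maximum(0, x - 10) * 1.0 + rng.normal(0, 0.1, 200)
        assert davies_test(x, y) < 0.001

    def test_degenerate_age_rejected(self):
        with pytest.raises(ValueError):
            davies_test(np.array([1.0, 1.0, 2.0, 2.0]), np.array([1.0, 2, 3, 4]))


class TestSegmentedFit:
    def test_noise_free_exact_recovery(self):
        spec = TrajectorySpec(intercept=1, slope_before=-0.1, psi=(10,),
                              delta=(-0.4,), noise_sd=0)
        x = np.linspace(1, 20, 300)
        fit = fit_segmented(x, spec.mean(x), 1)
        assert fit.psi[0] == pytest.approx(10.0, abs=1e-6)
        np.testing.assert_allclose(fit.slopes, [-0.1, -0.5], atol=1e-8)

    def test_slope_identity(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 20, 500)
        y = 1 - 0.1 * x - 0.3 * np.maximum(0, x - 9) + rng.normal(0, 0.3, 500)
        fit = fit_segmented(x, y, 1)
        assert fit.slopes[1] - fit.slopes[0] == pytest.approx(fit.delta[0], abs=1e-12)

    def test_per_segment_ols_oracle_noise_free(self):
        spec = TrajectorySpec(intercept=2, slope_before=-0.1, psi=(10,),
                              delta=(-0.4,), noise_sd=0)
        x = np.linspace(1, 20, 400)
        y = spec.mean(x)
        fit = fit_segmented(x, y, 1)
        tab = segment_slopes(fit)
        left = np.polyfit(x[x <= 10], y[x <= 10], 1)[0]
        right = np.polyfit(x[x > 10], y[x > 10], 1)[0]
        assert tab["slope"].iloc[0] == pytest.approx(left, abs=1e-8)
        assert tab["slope"].iloc[1] == pytest.approx(right, abs=1e-6)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = rng.uniform(1, 20, 250)
            psi = rng.uniform(5, 15)
            y = (1 - 0.05 * x - rng.uniform(0.05, 0.3) * np.maximum(0, x - psi)
                 + rng.normal(0, 0.5, 250))
            fit = fit_segmented(x, y, 1)
            assert fit.rss <= _grid_rss(x, y) * 1.001

    def test_two_breakpoint_recovery(self):
        oc = OldCurveSpec()
        mid = np.arange(1, 20) + 0.5
        fit = fit_segmented(mid, oc.probability(mid), 2)
        np.testing.assert_allclose(fit.psi, [5.85, 12.17], atol=1e-4)

    def test_one_sided_data_raises(self):
        with pytest.raises(ValueError):
            fit_segmented(np.array([1.0, 1.0, 1.0, 2.0]), np.array([1.0, 2, 1, 2]), 1)


class TestConfidenceIntervals:
    def test_width_shrinks_with_noise(self):
        rng = np.random.default_rng(7)
        widths = []
        for sd in (0.5, 0.05):
            x = rng.uniform(1, 20, 1000)
            y = 1 - 0.1 * x - 0.4 * np.maximum(0, x - 10) + rng.normal(0, sd, 1000)
            fit = fit_segmented(x, y, 1)
            lo, hi = breakpoint_confint(fit)[0]
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 3

    def test_formatting_matches_report_style(self):
        from dogaging.pipeline import _fmt_cell

        spec = TrajectorySpec(intercept=1, slope_before=-0.1, psi=(10.41,),
                              delta=(-0.3,), noise_sd=0)
        x = np.linspace(1, 20, 500)
        rng = np.random.default_rng(8)
        fit = fit_segmented(x, spec.mean(x) + rng.normal(0, 0.2, 500), 1)
        cell = _fmt_cell(fit, breakpoint_confint(fit))
        assert "(" in cell and "–" in cell


class TestCompareBreakpoints:
    def test_disjoint_differs(self):
        assert compare_breakpoints((8.0, 9.2), (9.9, 10.8)) is True

    def test_identical_does_not_differ(self):
        assert compare_breakpoints((9.9, 10.8), (9.9, 10.8)) is False

    def test_touching_endpoints_do_not_differ(self):
        assert compare_breakpoints((8.0, 9.0), (9.0, 10.0)) is False

    def test_undefined_interval_raises(self):
        with pytest.raises(ValueError):
            compare_breakpoints((np.nan, 1.0), (0.0, 1.0))


class TestSelection:
    def test_single_kink_selected(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            x = rng.uniform(1, 20, 400)
            y = 1 - 0.03 * x - 0.3 * np.maximum(0, x - 10) + rng.normal(0, 0.4, 400)
            if select_breakpoints(x, y).n_breakpoints == 1:
                hits += 1
        assert hits >= 18

    def test_null_mostly_zero(self):
        rng = np.random.default_rng(10)
        zeros = 0
        for _ in range(30):
            x = rng.uniform(1, 20, 200)
            y = 1 - 0.1 * x + rng.normal(0, 1, 200)
            if select_breakpoints(x, y).n_breakpoints == 0:
                zeros += 1
        assert zeros >= 25

    def test_two_change_point_curve_selected(self):
        oc = OldCurveSpec()
        mid = np.arange(1, 20) + 0.5
        rng = np.random.default_rng(11)
        prop = oc.probability(mid) + rng.normal(0, 0.01, len(mid))
        assert select_breakpoints(mid, prop).n_breakpoints == 2
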
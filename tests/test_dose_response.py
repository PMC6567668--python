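"""Quadratic/linear dose-response fitting and fixed-effects ANOVA."""

import numpy as np
import pytest
from scipy import stats

from soyco2 import fit_linear, fit_quadratic, one_way_anova, two_way_anova
from soyco2.errors import DomainError, FitError


class TestQuadratic:
    def test_exact_parabola_minimum(self):
        x = np.array([300.0, 500.0, 700.0, 900.0, 1100.0])
        y = (x - 600.0) ** 2 + 3.0
        fit = fit_quadratic(x, y)
        assert fit.x_opt == pytest.approx(600.0)
        assert fit.opt_kind == "minimum"
        assert fit.r2 == pytest.approx(1.0)
        assert not fit.extrapolated

    def test_exact_parabola_maximum(self):
        x = np.linspace(200, 1600, 8)
        y = -(x**2) + 1800.0 * x
        fit = fit_quadratic(x, y)
        assert fit.x_opt == pytest.approx(900.0)
        assert fit.opt_kind == "maximum"

    def test_noisy_vertex_recovery_within_10_percent(self):
        rng = np.random.default_rng(77)
        x = np.repeat(np.linspace(400, 1600, 7), 5)
        y_true = -((x - 900.0) ** 2) * 1e-4 + 30.0
        noise_sd = 0.05 * (y_true.max() - y_true.min())
        errs = [
            abs(fit_quadratic(x, y_true + rng.normal(0, noise_sd, x.size)).x_opt
                - 900.0) / 900.0
            for _ in range(30)
        ]
        assert np.median(errs) < 0.10

    def test_extrapolated_vertex_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 0.01 * x**2 + 100.0 * x  # vertex at -5000, far outside dose range
        fit = fit_quadratic(x, y)
        assert fit.extrapolated

    def test_shift_equivariance_and_y_scaling_invariance(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 12)
        y = -((x - 4.0) ** 2) + rng.normal(0, 0.1, 12)
        f0 = fit_quadratic(x, y)
        f_shift = fit_quadratic(x + 100.0, y)
        f_scale = fit_quadratic(x, 7.3 * y)
        assert f_shift.x_opt == pytest.approx(f0.x_opt + 100.0, abs=1e-6)
        assert f_scale.x_opt == pytest.approx(f0.x_opt, abs=1e-8)
        assert f_scale.r2 == pytest.approx(f0.r2, abs=1e-10)

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(FitError):
            fit_quadratic([1, 1, 2, 2, 3, 3], [1, 2, 3, 4, 5, 6])


class TestLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        fit = fit_linear(np.arange(6.0), np.full(6, 3.3))
        assert fit.slope == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(0.0)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(FitError):
            fit_linear([2, 2, 2, 2], [1, 2, 3, 4])

    def test_slope_ci_coverage_near_95_percent(self):
        rng = np.random.default_rng(321)
        cover = 0
        n, trials = 20, 200
        for _ in range(trials):
            x = np.linspace(0, 1, n)
            y = 2.0 * x + rng.normal(0, 0.5, n)
            res = stats.linregress(x, y)
            half = stats.t.ppf(0.975, n - 2) * res.stderr
            if abs(res.slope - 2.0) <= half:
                cover += 1
        assert 0.90 <= cover / trials <= 0.99


class TestOneWayAnova:
    def test_hand_computed_f(self):
        res = one_way_anova([(1, 2, 3), (4, 5, 6)])["factor"]
        assert res.f == pytest.approx(13.5)
        assert (res.df_num, res.df_den) == (1, 4)

    def test_equal_means_give_zero_f(self):
        res = one_way_anova([(1.0, 3.0), (2.0, 2.0), (1.5, 2.5)])["factor"]
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            one_way_anova([(1, 2, 3)])

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
        f = one_way_anova([a, b])["factor"].f
        t = stats.ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 6) for m in (0, 0.5, 1.0)]
        mine = one_way_anova(groups)["factor"]
        ref = stats.f_oneway(*groups)
        assert mine.f == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)


def _balanced_cells(rng, a=2, b=2, r=5, interaction=0.0, sigma=1.0):
    cells = {}
    for i in range(a):
        for j in range(b):
            mu = i * 1.0 + j * 0.5 + (interaction if (i and j) else 0.0)
            cells[(f"a{i}", f"b{j}")] = rng.normal(mu, sigma, r)
    return cells


class TestTwoWayAnova:
    def test_additive_means_no_noise_zero_interaction(self):
        cells = {
            ("a0", "b0"): [1.0, 1.0],
            ("a0", "b1"): [2.0, 2.0],
            ("a1", "b0"): [3.0, 3.0],
            ("a1", "b1"): [4.0, 4.0],
        }
        # perfectly additive and noiseless: interaction SS is exactly 0
        res = two_way_anova(cells)
        assert res["A:B"].f == pytest.approx(0.0, abs=1e-18)

    def test_missing_cell_rejected(self):
        cells = {("a0", "b0"): [1, 2], ("a0", "b1"): [1, 2], ("a1", "b0"): [1, 2]}
        with pytest.raises(DomainError, match="missing cells"):
            two_way_anova(cells)

    def test_unbalanced_rejected(self):
        cells = _balanced_cells(np.random.default_rng(0))
        cells[("a0", "b0")] = cells[("a0", "b0")][:3]
        with pytest.raises(DomainError, match="unbalanced"):
            two_way_anova(cells)

    def test_matches_statsmodels(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(42)
        cells = _balanced_cells(rng, a=3, b=2, r=4, interaction=1.0)
        res = two_way_anova(cells)
        rows = [
            {"A": ka, "B": kb, "y": v}
            for (ka, kb), vals in cells.items()
            for v in vals
        ]
        df = pd.DataFrame(rows)
        table = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", df).fit(), typ=2)
        assert res["A"].f == pytest.approx(table.loc["C(A)", "F"], rel=1e-9)
        assert res["B"].f == pytest.approx(table.loc["C(B)", "F"], rel=1e-9)
        assert res["A:B"].f == pytest.approx(
            table.loc["C(A):C(B)", "F"], rel=1e-9
        )

    def test_interaction_power_at_3_sigma(self):
        rng = np.random.default_rng(123)
        detected = sum(
            two_way_anova(
                _balanced_cells(rng, r=5, interaction=3.0, sigma=1.0)
            )["A:B"].p < 0.05
            for _ in range(100)
        )
        assert detected >= 80

    def test_type_one_error_near_alpha_under_null(self):
        rng = np.random.default_rng(2718)
        reps = 1000
        false_pos = sum(
            two_way_anova(_balanced_cells(rng, interaction=0.0))["A:B"].p < 0.05
            for _ in range(reps)
        )
        assert abs(false_pos / reps - 0.05) <= 0.02

    def test_one_way_type_one_error_near_alpha_under_null(self):
        rng = np.random.default_rng(314)
        reps = 1000
        false_pos = sum(
            one_way_anova([rng.normal(0, 1, 5) for _ in range(4)])["factor"].p
            < 0.05
            for _ in range(reps)
        )
        assert abs(false_pos / reps - 0.05) <= 0.02
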
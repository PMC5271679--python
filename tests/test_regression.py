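"""CI-weighted linear regressions, interaction test and growth-rate fit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import photoinact as pi


def _ols_closed_form(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return b, y.mean() - b * x.mean()


class TestWeightedLinearFit:
    def test_exact_line_any_weights(self):
        x = np.arange(6.0)
        y = 2.0 * x + 1.0
        ci = np.array([0.1, 3.0, 0.5, 7.0, 0.2, 1.0])
        res = pi.weighted_linear_fit(x, y, ci)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_equal_weights_match_ols(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 1, 12)
        y = 0.3 * x + 0.1 + rng.normal(0, 0.05, 12)
        res = pi.weighted_linear_fit(x, y, np.full(12, 0.7))
        slope, intercept = _ols_closed_form(x, y)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)

    def test_noiseless_generated_line_recovered_exactly(self):
        """Yield-vs-pressure line with realistic magnitudes, zero noise."""
        df = pi.make_regression_set(3.731e-7, 4.046e-7,
                                    np.linspace(0.1, 0.9, 9), noise_sd=0.0)
        res = pi.weighted_linear_fit(df.x, df.rate, df.rate_ci95)
        assert res.slope == pytest.approx(3.731e-7, rel=1e-9)
        assert res.intercept == pytest.approx(4.046e-7, rel=1e-9)

    def test_scale_equivariance(self):
        df = pi.make_regression_set(3.7e-7, 4.0e-7, np.linspace(0.1, 0.9, 8),
                                    noise_sd=8e-8, seed=3)
        a = pi.weighted_linear_fit(df.x, df.rate, df.rate_ci95)
        c = 1e6
        b = pi.weighted_linear_fit(df.x, df.rate * c, df.rate_ci95 * c)
        assert b.slope == pytest.approx(a.slope * c, rel=1e-9)
        assert b.intercept == pytest.approx(a.intercept * c, rel=1e-9)
        assert b.r_squared == pytest.approx(a.r_squared, rel=1e-9)
        assert b.slope_p == pytest.approx(a.slope_p, rel=1e-6)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            pi.weighted_linear_fit([1.0, 1.0, 1.0], [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            pi.weighted_linear_fit([1.0, 2.0], [1, 2], [1, 1])
        with pytest.raises(ValueError):
            pi.weighted_linear_fit([1, 2, 3], [1, 2, 3], [1, 0, 1])

    @given(c=st.floats(0.1, 50.0))
    def test_weight_scale_leaves_estimates(self, c):
        df = pi.make_regression_set(2.0, 1.0, np.linspace(0, 1, 6),
                                    noise_sd=0.1, seed=5)
        a = pi.weighted_linear_fit(df.x, df.rate, df.rate_ci95)
        b = pi.weighted_linear_fit(df.x, df.rate, df.rate_ci95 * c)
        assert b.slope == pytest.approx(a.slope, rel=1e-9)


class TestInteraction:
    def test_identical_lines_zero_interaction(self):
        x = np.tile(np.linspace(0.1, 0.9, 5), 2)
        y = 3.0 * x + 1.0
        g = ["A"] * 5 + ["B"] * 5
        res = pi.interaction_test(x, y, np.full(10, 0.5), g)
        assert res["params"]["x:group"] == pytest.approx(0.0, abs=1e-9)
        assert res["params"]["group"] == pytest.approx(0.0, abs=1e-9)

    def test_slope_difference_recovered(self):
        xa = np.linspace(0.1, 0.9, 6)
        y = np.concatenate([2.0 * xa + 1.0, 4.0 * xa + 1.0])
        x = np.tile(xa, 2)
        g = ["A"] * 6 + ["B"] * 6
        res = pi.interaction_test(x, y, np.full(12, 0.5), g)
        assert res["params"]["x:group"] == pytest.approx(2.0, rel=1e-9)
        assert res["params"]["x"] == pytest.approx(2.0, rel=1e-9)

    def test_single_group_rejected(self):
        x = np.linspace(0, 1, 6)
        with pytest.raises(ValueError):
            pi.interaction_test(x, x, np.full(6, 0.5), ["A"] * 6)
        with pytest.raises(ValueError):
            pi.interaction_test(x, x, np.full(6, 0.5),
                                ["A"] * 4 + ["B"] * 2)

    def test_type_i_error_rate_under_true_null(self):
        """False-positive interaction rate stays near alpha over 500 reps."""
        x_design = np.linspace(0.1, 0.9, 8)
        rejections = 0
        for rep in range(500):
            a = pi.make_regression_set(3.7e-7, 4.0e-7, x_design,
                                       noise_sd=8e-8, seed=2 * rep)
            b = pi.make_regression_set(3.7e-7, 4.0e-7, x_design,
                                       noise_sd=8e-8, seed=2 * rep + 1)
            res = pi.interaction_test(
                np.concatenate([a.x, b.x]),
                np.concatenate([a.rate, b.rate]),
                np.concatenate([a.rate_ci95, b.rate_ci95]),
                ["A"] * len(a) + ["B"] * len(b))
            rejections += res["interaction_p"] < 0.05
        assert rejections / 500 <= 0.07


class TestGrowthRate:
    def test_doubling_per_day(self):
        t = np.arange(6.0)
        res = pi.fit_exponential_growth(t, 100.0 * 2.0 ** t)
        assert res["mu_per_day"] == pytest.approx(np.log(2), rel=1e-9)

    def test_constant_rfu_zero_growth(self):
        res = pi.fit_exponential_growth(np.arange(5.0), np.full(5, 40.0))
        assert res["mu_per_day"] == pytest.approx(0.0, abs=1e-12)

    def test_exponential_construction(self):
        t = np.linspace(0, 7, 8)
        res = pi.fit_exponential_growth(t, 100.0 * np.exp(0.3 * t))
        assert res["mu_per_day"] == pytest.approx(0.3, rel=1e-9)
        assert res["rfu0"] == pytest.approx(100.0, rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pi.fit_exponential_growth([0, 1, 2], [1.0, -1.0, 2.0])
        with pytest.raises(ValueError):
            pi.fit_exponential_growth([0, 2, 1], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pi.fit_exponential_growth([0, 1], [1.0, 2.0])
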
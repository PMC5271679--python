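"""CI-weighted linear regressions and the exponential growth-rate fit.

Per-treatment photoinactivation estimates (sigma_i or Phi_i PSII) are
regressed against treatment intensity or excitation pressure, each point
weighted by the inverse of its 95% confidence half-width so imprecise fits
count less.  Weights are treated as relative (the residual variance is
re-estimated), matching R's lm/nls behaviour; reported "±" values are
standard errors.  An interaction test asks whether a binary grouping
(species, growth light) changes the regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "weighted_linear_fit", "interaction_test",
           "fit_exponential_growth"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci95: float
    intercept_ci95: float
    slope_p: float
    intercept_p: float
    r_squared: float
    n: int
    weighting: str

    @property
    def intercept_nonzero(self) -> bool:
        """Whether the intercept differs from zero at p < 0.05."""
        return self.intercept_p < 0.05


def _check_weights(ci95: np.ndarray, weighting: str) -> np.ndarray:
    if np.any(ci95 <= 0):
        raise ValueError("ci95 half-widths must be > 0")
    if weighting == "inverse_ci":
        return 1.0 / ci95
    if weighting == "inverse_ci_squared":
        return 1.0 / ci95**2
    raise ValueError("weighting must be 'inverse_ci' or 'inverse_ci_squared'")


def weighted_linear_fit(x, y, ci95=None,
                        weighting: str = "inverse_ci") -> RegressionResult:
    """Weighted least-squares line y = a + b x with 1/CI weights.

    With ``ci95=None`` (or equal half-widths) this reduces to ordinary
    least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x has no spread")
    if ci95 is None:
        w = np.ones_like(x)
        weighting = "none"
    else:
        ci95 = np.asarray(ci95, dtype=float)
        if ci95.shape != x.shape:
            raise ValueError("ci95 must match x in length")
        w = _check_weights(ci95, weighting)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    ci = res.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
        slope_ci95=float(res.params[1] - ci[1, 0]),
        intercept_ci95=float(res.params[0] - ci[0, 0]),
        slope_p=float(res.pvalues[1]), intercept_p=float(res.pvalues[0]),
        r_squared=float(res.rsquared), n=int(x.size), weighting=weighting)


def interaction_test(x, y, ci95, group,
                     weighting: str = "inverse_ci") -> dict:
    """Weighted linear model y ~ x * group for a binary grouping factor.

    Returns the fitted coefficients plus p-values for the group main effect
    and the x:group interaction (does the grouping shift the line or change
    its slope?).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ci95 = np.asarray(ci95, dtype=float)
    labels = pd.Categorical(np.asarray(group))
    if len(labels.categories) != 2:
        raise ValueError("group must have exactly 2 levels")
    g = labels.codes.astype(float)
    for lvl in (0, 1):
        if np.sum(g == lvl) < 3:
            raise ValueError("both groups need at least 3 points")
    w = _check_weights(ci95, weighting)
    design = np.column_stack((np.ones_like(x), x, g, x * g))
    res = sm.WLS(y, design, weights=w).fit()
    return {
        "params": {"intercept": float(res.params[0]), "x": float(res.params[1]),
                   "group": float(res.params[2]),
                   "x:group": float(res.params[3])},
        "group_p": float(res.pvalues[2]),
        "interaction_p": float(res.pvalues[3]),
        "group_levels": list(labels.categories),
        "r_squared": float(res.rsquared),
        "n": int(x.size),
        "summary": res,
    }


def fit_exponential_growth(time_days, rfu) -> dict:
    """Exponential growth rate µ (d⁻¹) from RFU_t = RFU_0 exp(µ t).

    µ is the slope of the ordinary regression of ln(RFU) on time.
    """
    t = np.asarray(time_days, dtype=float)
    rfu = np.asarray(rfu, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if np.any(rfu <= 0):
        raise ValueError("RFU must be > 0")
    res = sm.OLS(np.log(rfu), sm.add_constant(t)).fit()
    ci = res.conf_int(alpha=0.05)
    return {
        "mu_per_day": float(res.params[1]),
        "mu_ci95": float(res.params[1] - ci[1, 0]),
        "rfu0": float(np.exp(res.params[0])),
        "r_squared": float(res.rsquared),
        "n": int(t.size),
    }
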
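"""Sustained-NPQ correction and single-phase exponential photoinactivation fits.

With PSII repair blocked (lincomycin), the maximum photochemical yield
measured 2 s after each light period, FV'2s/FM'2s, declines with cumulative
photon dose because photoinactivated centres accumulate.  Two nested
kinetic parameterisations are fitted:

    FV'2s/FM'2s = (FV'2s/FM'2s)_t=0 * exp(-sigma_i * cumulative incident quanta Å⁻²)
    FV'2s/FM'2s = (FV'2s/FM'2s)_t=0 * exp(-Phi_i_PSII * cumulative photons PSII⁻¹)

sigma_i (Å² quanta⁻¹) is a target size per photon incident on the cell;
Phi_i PSII (dimensionless) is the yield of photoinactivations per photon
delivered to PSII photochemistry through sigma_PSII'2s.

Sustained NPQ that persists through the 2 s dark intervals depresses the
measured yields; its influence is estimated as the rise from the final
treatment period to the terminal low-light recovery period (floored at 0)
and added back to every treatment-period value before fitting.

Each point is weighted by the inverse of its 95% confidence half-width
(weight applied to the squared residual, as in R's nls); an inverse-variance
(1/CI²) option is available for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np
from scipy import optimize, stats

from .dose import TreatmentProtocol, DoseSeries, dose_series

__all__ = [
    "TreatmentTimeCourse",
    "DecayFit",
    "MissingRecoveryPeriodError",
    "sustained_npq_influence",
    "apply_npq_correction",
    "fit_sigma_i",
    "fit_phi_i",
]

_EPS = 1e-9


class MissingRecoveryPeriodError(ValueError):
    """Raised when the NPQ correction is requested without a recovery period.

    Pass ``npq_influence=0`` explicitly (or a protocol with a recovery
    period) to override.
    """


@dataclass(frozen=True)
class TreatmentTimeCourse:
    """Per-period photophysiology through one light-shift treatment.

    One record per protocol period, in order, starting at period 1.  The
    2 s-dark quantities (F0'2s, FM'2s, sigma_PSII'2s, FV'2s/FM'2s) are the
    basis of the photoinactivation fits; the under-actinic levels (FS, FM')
    feed the excitation-pressure calculation.
    """

    protocol: TreatmentProtocol
    fv_fm_2s: np.ndarray
    fv_fm_2s_ci95: np.ndarray
    sigma_psii_2s: np.ndarray
    f0_prime_2s: np.ndarray | None = None
    fm_prime_2s: np.ndarray | None = None
    fs: np.ndarray | None = None
    fm_prime: np.ndarray | None = None
    f0: float | None = None       # dark-adapted levels from period 1
    fm: float | None = None
    species: str = ""
    growth_light: float = float("nan")
    treat_colour: str = ""
    treat_intensity: float = float("nan")
    npq_influence_applied: float | None = None
    ground_truth: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        n = self.protocol.n_periods
        for name in ("fv_fm_2s", "fv_fm_2s_ci95", "sigma_psii_2s",
                     "f0_prime_2s", "fm_prime_2s", "fs", "fm_prime"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (n,):
                raise ValueError(f"{name} must have one value per period ({n})")
        if np.any(self.fv_fm_2s <= 0) or np.any(self.fv_fm_2s >= 1):
            raise ValueError("fv_fm_2s must lie in (0, 1)")
        if np.any(self.fv_fm_2s_ci95 <= 0):
            raise ValueError("fv_fm_2s_ci95 must be > 0")

    @property
    def periods(self) -> np.ndarray:
        return np.arange(1, self.protocol.n_periods + 1)

    @property
    def elapsed_s(self) -> np.ndarray:
        return self.protocol.t_end_s


@dataclass(frozen=True)
class DecayFit:
    """Single-phase exponential decay fit of FV'2s/FM'2s against dose."""

    rate: float                 # sigma_i (Å² quanta⁻¹) or Phi_i PSII (dimensionless)
    amplitude: float            # FV'2s/FM'2s at zero dose
    rate_ci95: float
    amplitude_ci95: float
    r_squared: float
    basis: str                  # "incident" | "delivered"
    npq_influence_applied: float
    n_points: int

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("decay rate must be >= 0")
        if not (0 < self.amplitude < 1):
            raise ValueError("amplitude must lie in (0, 1)")


def sustained_npq_influence(fv_fm_recovery: float,
                            fv_fm_treatment_end: float) -> float:
    """Sustained-NPQ influence on photochemical yield, floored at zero.

    The difference between FV'2s/FM'2s after the terminal low-light reversal
    period and after the last treatment period; negative values mean no
    resolvable sustained NPQ and are forced to 0.
    """
    for v in (fv_fm_recovery, fv_fm_treatment_end):
        if not 0 < v < 1:
            raise ValueError("yields must lie in (0, 1)")
    return max(0.0, fv_fm_recovery - fv_fm_treatment_end)


def apply_npq_correction(tc: TreatmentTimeCourse,
                         npq_influence: float | None = None) -> TreatmentTimeCourse:
    """Add the sustained-NPQ influence back to treatment-period yields.

    The influence is estimated from the recovery-period versus
    final-treatment-period measurements unless given explicitly.  Corrected
    values are capped just below 1; CI half-widths are unchanged.
    """
    kinds = tc.protocol.kinds
    if npq_influence is None:
        if "recovery" not in kinds:
            raise MissingRecoveryPeriodError(
                "protocol has no recovery period; pass npq_influence=0 to "
                "skip the sustained-NPQ correction")
        i_rec = len(kinds) - 1 - kinds[::-1].index("recovery")
        treat = [i for i, k in enumerate(kinds) if k == "treatment"]
        if not treat:
            raise ValueError("protocol has no treatment periods")
        npq_influence = sustained_npq_influence(
            tc.fv_fm_2s[i_rec], tc.fv_fm_2s[treat[-1]])
    if npq_influence < 0:
        raise ValueError("npq_influence must be >= 0")
    corrected = tc.fv_fm_2s.copy()
    for i, k in enumerate(kinds):
        if k == "treatment":
            corrected[i] = min(corrected[i] + npq_influence, 1.0 - _EPS)
    return replace(tc, fv_fm_2s=corrected, npq_influence_applied=float(npq_influence))


def _weights(ci95: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "inverse_ci":
        return 1.0 / ci95
    if scheme == "inverse_ci_squared":
        return 1.0 / ci95**2
    raise ValueError("weighting must be 'inverse_ci' or 'inverse_ci_squared'")


def _fit_points(tc: TreatmentTimeCourse) -> np.ndarray:
    """0-based indices of periods entering the decay fit.

    All dose-accruing periods (growth + treatment) plus the initial dark
    period, which anchors the zero-dose end; recovery periods are excluded.
    """
    return np.array([i for i, k in enumerate(tc.protocol.kinds)
                     if k != "recovery"])


def _exp_decay_wls(x: np.ndarray, y: np.ndarray,
                   w: np.ndarray) -> tuple[float, float, np.ndarray, float]:
    """Weighted NLS of y = A exp(-k x); returns (A, k, cov, R²).

    Analytic Jacobian; k bounded at 0 (a rising series pins k to the bound).
    Deterministic initialisation from a log-linear regression of ln y on x.
    """
    sw = np.sqrt(w)
    # log-linear init
    ly = np.log(np.clip(y, 1e-12, None))
    slope, intercept = np.polyfit(x, ly, 1)
    k0 = max(-slope, 0.0)
    a0 = float(np.clip(np.exp(intercept), 1e-6, 1.0 - 1e-6))

    def resid(p: np.ndarray) -> np.ndarray:
        a, k = p
        return sw * (a * np.exp(-k * x) - y)

    def jac(p: np.ndarray) -> np.ndarray:
        a, k = p
        e = np.exp(-k * x)
        return np.column_stack((sw * e, -sw * a * x * e))

    sol = optimize.least_squares(
        resid, np.array([a0, k0]), jac=jac,
        bounds=([1e-9, 0.0], [1.0 - 1e-9, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=1000)
    if not sol.success:
        raise RuntimeError(f"decay fit did not converge: {sol.message}")
    a, k = sol.x
    dof = max(x.size - 2, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    ybar = np.sum(w * y) / np.sum(w)
    sst = float(np.sum(w * (y - ybar) ** 2))
    ssr = float(np.sum(w * (a * np.exp(-k * x) - y) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return float(a), float(k), cov, r2


def _fit_decay(tc: TreatmentTimeCourse, x_full: np.ndarray, basis: str,
               weighting: str) -> DecayFit:
    idx = _fit_points(tc)
    if idx.size < 4:
        raise ValueError("need at least 4 dose-accruing points to fit a decay")
    x = np.asarray(x_full, dtype=float)[idx]
    y = tc.fv_fm_2s[idx]
    ci = tc.fv_fm_2s_ci95[idx]
    if not np.all(np.isfinite(ci)):
        raise ValueError("all fitted points need finite CI half-widths")
    w = _weights(ci, weighting)
    a, k, cov, r2 = _exp_decay_wls(x, y, w)
    if k * float(np.max(x)) < 1e-9 and np.polyfit(x, np.log(y), 1)[0] > 1e-12:
        warnings.warn("series rises with dose; decay rate pinned at 0",
                      stacklevel=2)
    tq = stats.t.ppf(0.975, max(x.size - 2, 1))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return DecayFit(rate=k, amplitude=a,
                    rate_ci95=float(tq * se[1]), amplitude_ci95=float(tq * se[0]),
                    r_squared=r2, basis=basis,
                    npq_influence_applied=float(tc.npq_influence_applied or 0.0),
                    n_points=int(x.size))


def fit_sigma_i(tc: TreatmentTimeCourse, ds: DoseSeries | None = None,
                weighting: str = "inverse_ci") -> DecayFit:
    """Fit sigma_i against cumulative incident photons (quanta Å⁻²).

    ``tc`` should already carry the sustained-NPQ correction
    (:func:`apply_npq_correction`); the fit itself is agnostic.
    """
    if ds is None:
        ds = dose_series(tc.protocol)
    return _fit_decay(tc, ds.cumulative_A2, "incident", weighting)


def fit_phi_i(tc: TreatmentTimeCourse, ds: DoseSeries | None = None,
              weighting: str = "inverse_ci") -> DecayFit:
    """Fit Phi_i PSII against cumulative photons delivered to PSII.

    Delivered dose accrues as each period's incident dose (quanta Å⁻²)
    times that period's measured sigma_PSII'2s (Å² quanta⁻¹).
    """
    if ds is None:
        ds = dose_series(tc.protocol)
    if ds.cumulative_delivered is None:
        ds = ds.with_delivered(tc.sigma_psii_2s)
    return _fit_decay(tc, ds.cumulative_delivered, "delivered", weighting)
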
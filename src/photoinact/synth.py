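"""Ground-truth-known synthetic datasets for every pipeline level.

Generates the three kinds of records the analysis consumes: flashlet-level
FRR induction traces, per-period treatment time courses (the FV'2s/FM'2s
decay series with confidence intervals), and multi-treatment regression
tables.  Every generator draws from a single seeded NumPy generator, so a
preset plus a seed fully determines the dataset, and the generating
parameters travel with the output for recovery checks.

The forward model of a time course is the same kinetics the fitting modules
invert: yields decay as exp(-sigma_i x cumulative incident quanta Å⁻²) over
the dose-accruing periods, sustained NPQ depresses treatment-period values
by a fixed offset that relaxes in the terminal low-light period, and the
20 µmol photons m⁻² s⁻¹ recovery period is taken to add negligible
photoinactivation dose.  Measurement noise is additive Gaussian on the
fluorescence levels (F0'2s, FM'2s) and multiplicative on sigma_PSII'2s;
confidence half-widths are propagated from the level noise and floored to
avoid infinite weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .decay import TreatmentTimeCourse
from .dose import TreatmentProtocol, dose_series
from .induction import FlashletTrain, InductionFit, InductionTrace, simulate_induction
from .quenching import f0_prime

__all__ = [
    "ScenarioPreset", "FIG3_BLUE", "FIG3_RED", "PRESETS",
    "make_timecourse", "make_regression_set", "make_budget_scenario",
]

_CI_FLOOR = 1e-3


@dataclass(frozen=True)
class ScenarioPreset:
    """Generating parameters for one synthetic light-shift treatment.

    ``sigma_psii_2s`` is held constant across periods by default, which
    makes the delivered-dose yield identity Phi_i = sigma_i / sigma_PSII'2s
    exact; ``sigma_drift`` adds a linear per-period decline to emulate
    light acclimation.  Noise defaults: additive Gaussian sd 0.01 on
    fluorescence levels, 2% relative sd on sigma_PSII'2s.
    """

    name: str
    species: str
    growth_light: float            # µmol photons m⁻² s⁻¹
    treat_colour: str
    treat_intensity: float
    sigma_i: float                 # Å² quanta⁻¹, ground truth
    sigma_psii_2s: float           # Å² quanta⁻¹
    f0: float = 0.45
    fm: float = 1.0
    npq_influence: float = 0.02
    one_minus_qp: float = 0.55
    noise_sd: float = 0.01
    sigma_rel_sd: float = 0.02
    sigma_drift: float = 0.0       # fractional decline per period
    n_treatment: int = 7
    period_s: float = 327.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fm > self.f0 > 0):
            raise ValueError("require FM > F0 > 0")
        if self.sigma_i < 0 or self.sigma_psii_2s <= 0:
            raise ValueError("cross sections must be positive")
        if not 0 <= self.one_minus_qp <= 1:
            raise ValueError("1-qP must lie in [0, 1]")
        if min(self.noise_sd, self.sigma_rel_sd) < 0 or self.npq_influence < 0:
            raise ValueError("noise and NPQ parameters must be >= 0")

    @property
    def phi_i(self) -> float:
        """Implied yield per delivered photon (constant-sigma case)."""
        return self.sigma_i / self.sigma_psii_2s

    @property
    def amplitude(self) -> float:
        return (self.fm - self.f0) / self.fm

    def protocol(self) -> TreatmentProtocol:
        return TreatmentProtocol.standard(
            self.growth_light, self.treat_intensity, self.treat_colour,
            n_treatment=self.n_treatment, period_s=self.period_s)

    def noiseless(self) -> "ScenarioPreset":
        return replace(self, noise_sd=0.0, sigma_rel_sd=0.0)


# Representative treatments: Prochlorococcus grown at 260 µmol photons
# m⁻² s⁻¹, shifted to 1200 µmol photons m⁻² s⁻¹ of blue or red light.
# sigma_PSII'2s is set so the incident- and delivered-dose yields are
# mutually consistent (sigma_i / Phi_i).
FIG3_BLUE = ScenarioPreset(
    name="fig3-blue", species="Prochlorococcus marinus MED4",
    growth_light=260.0, treat_colour="blue_455nm", treat_intensity=1200.0,
    sigma_i=1.23e-4, sigma_psii_2s=1.23e-4 / 7.2e-7,
    one_minus_qp=0.60, seed=31)

FIG3_RED = ScenarioPreset(
    name="fig3-red", species="Prochlorococcus marinus MED4",
    growth_light=260.0, treat_colour="red_655nm", treat_intensity=1200.0,
    sigma_i=1.65e-5, sigma_psii_2s=1.65e-5 / 2.8e-7,
    one_minus_qp=0.45, seed=32)

PRESETS = {p.name: p for p in (FIG3_BLUE, FIG3_RED)}


def _effective_cumulative_A2(protocol: TreatmentProtocol) -> np.ndarray:
    """Photoinactivation-effective cumulative dose: recovery does not accrue."""
    ds = dose_series(protocol)
    eff = ds.cumulative_A2.copy()
    last = 0.0
    for i, kind in enumerate(protocol.kinds):
        if kind == "recovery":
            eff[i] = last
        else:
            last = eff[i]
    return eff


def make_timecourse(preset: ScenarioPreset,
                    with_traces: bool = False,
                    train: FlashletTrain | None = None,
                    ) -> TreatmentTimeCourse | tuple[TreatmentTimeCourse, list[InductionTrace]]:
    """Simulate one treatment time course from ground-truth parameters.

    Returns a :class:`TreatmentTimeCourse` whose ``ground_truth`` dict
    records the generating parameters.  With ``with_traces`` also returns
    one simulated after-2s-dark induction trace per period, generated from
    the same per-period fluorescence levels so that flashlet-level fits
    reproduce the period-level parameters.
    """
    rng = np.random.default_rng(preset.seed)
    protocol = preset.protocol()
    n = protocol.n_periods
    kinds = protocol.kinds

    eff = _effective_cumulative_A2(protocol)
    y_true = preset.amplitude * np.exp(-preset.sigma_i * eff)
    y_meas = y_true.copy()
    treat_mask = np.array([k == "treatment" for k in kinds])
    y_meas[treat_mask] -= preset.npq_influence
    if np.any(y_meas <= 0):
        raise ValueError("NPQ influence drives yields non-positive")

    # 2s-dark fluorescence levels consistent with the yields
    f0_2s_true = np.full(n, preset.f0)
    fm_2s_true = preset.f0 / (1.0 - y_meas)
    f0_2s = f0_2s_true + rng.normal(0.0, preset.noise_sd, n)
    fm_2s = fm_2s_true + rng.normal(0.0, preset.noise_sd, n)
    f0_2s = np.clip(f0_2s, 1e-3, None)
    fm_2s = np.maximum(fm_2s, f0_2s * (1.0 + 1e-6))
    fv_fm = 1.0 - f0_2s / fm_2s
    fv_fm = np.clip(fv_fm, 1e-6, 1.0 - 1e-6)
    ratio = f0_2s / fm_2s
    ci95 = np.maximum(
        1.96 * preset.noise_sd * np.sqrt(1.0 + ratio**2) / fm_2s, _CI_FLOOR)

    drift = 1.0 - preset.sigma_drift * np.arange(n)
    sigma = preset.sigma_psii_2s * drift * (
        1.0 + rng.normal(0.0, preset.sigma_rel_sd, n))
    sigma = np.clip(sigma, 1e-6, None)

    # under-actinic levels pinned to the target excitation pressure
    fm_prime = 0.9 * fm_2s_true
    f0p = f0_prime(preset.f0, preset.fm, fm_2s_true)
    fs = f0p + preset.one_minus_qp * (fm_prime - f0p)
    fm_prime[0], fs[0] = preset.fm, preset.f0  # dark period: no actinic light

    tc = TreatmentTimeCourse(
        protocol=protocol, fv_fm_2s=fv_fm, fv_fm_2s_ci95=ci95,
        sigma_psii_2s=sigma, f0_prime_2s=f0_2s, fm_prime_2s=fm_2s,
        fs=fs, fm_prime=fm_prime, f0=preset.f0, fm=preset.fm,
        species=preset.species, growth_light=preset.growth_light,
        treat_colour=preset.treat_colour, treat_intensity=preset.treat_intensity,
        ground_truth={
            "preset": preset.name, "sigma_i": preset.sigma_i,
            "phi_i": preset.phi_i, "amplitude": preset.amplitude,
            "npq_influence": preset.npq_influence,
            "one_minus_qp": preset.one_minus_qp,
            "sigma_psii_2s": preset.sigma_psii_2s, "seed": preset.seed,
        })
    if not with_traces:
        return tc

    train = train or FlashletTrain()
    traces = []
    for i in range(n):
        params = InductionFit(f0=float(f0_2s_true[i]), fm=float(fm_2s_true[i]),
                              sigma_psii=float(sigma[i]), rho=0.0)
        traces.append(simulate_induction(
            params, train, noise_sd=preset.noise_sd,
            seed=int(rng.integers(2**31)), context="after_2s_dark"))
    return tc, traces


def make_regression_set(slope: float, intercept: float, x_design,
                        noise_sd: float = 0.0, n_reps: int = 1,
                        seed: int | None = None,
                        ci_floor: float = 1e-9) -> pd.DataFrame:
    """Synthetic per-treatment rate estimates on a known line.

    ``rate = intercept + slope * x`` plus heteroscedastic Gaussian noise:
    each point's sd is noise_sd scaled by a uniform factor in [0.5, 1.5],
    and the reported 95% half-width is 1.96 x that sd, so inverse-CI
    weighting genuinely matters.  Ground truth lands in ``DataFrame.attrs``.
    """
    x_design = np.asarray(x_design, dtype=float)
    if np.ptp(x_design) == 0:
        raise ValueError("x_design must have spread")
    rng = np.random.default_rng(seed)
    x = np.tile(x_design, n_reps)
    sd = noise_sd * rng.uniform(0.5, 1.5, x.size)
    rate = intercept + slope * x + rng.normal(0.0, 1.0, x.size) * sd
    df = pd.DataFrame({
        "x": x,
        "rate": rate,
        "rate_ci95": np.maximum(1.96 * sd, ci_floor),
    })
    df.attrs["ground_truth"] = {"slope": slope, "intercept": intercept,
                                "noise_sd": noise_sd, "seed": seed}
    return df


def make_budget_scenario(intensities,
                         sigma_psii_2s: float = 250.0,
                         ek: float = 300.0,
                         sigma_i_intercept: float = 3.75e-5,
                         sigma_i_slope: float = 1.0e-7,
                         colour: str = "blue_455nm",
                         species: str = "Synechococcus-like") -> list[dict]:
    """Per-intensity inputs for the cost-benefit budget.

    A Synechococcus-like scenario: large antenna cross section, open-centre
    fraction declining as qP = 1/(1 + I/Ek) with a light-saturation
    parameter Ek, and a photoinactivation target size rising linearly with
    intensity as observed for blue-light treatments.
    """
    records = []
    for i in np.asarray(intensities, dtype=float):
        records.append({
            "species": species, "colour": colour, "intensity": float(i),
            "sigma_psii_2s": sigma_psii_2s,
            "qp": 1.0 / (1.0 + i / ek),
            "sigma_i": sigma_i_intercept + sigma_i_slope * i,
        })
    return records
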
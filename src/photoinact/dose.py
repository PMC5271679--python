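"""Light-shift treatment protocol and cumulative photon dose bookkeeping.

The photoinactivation protocol is a sequence of constant-intensity periods:
by default ten 327 s periods — dark, growth irradiance, seven treatment
periods, and a terminal 20 µmol photons m⁻² s⁻¹ low-light recovery period
that lets sustained non-photochemical quenching relax.

Cumulative incident photons through period n sum intensity x duration over
periods 2..n (the initial dark period is excluded by convention; it emits no
photons anyway).  Delivered photons per PSII multiply each period's incident
dose (quanta Å⁻²) by the effective absorption cross section sigma_PSII'2s
(Å² quanta⁻¹) measured for that period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import PHOTONS_PER_UMOL, A2_PER_M2

__all__ = [
    "Period",
    "TreatmentProtocol",
    "DoseSeries",
    "cumulative_incident_photons",
    "dose_series",
    "delivered_photons_per_psii",
]

_KINDS = ("dark", "growth", "treatment", "recovery")


@dataclass(frozen=True)
class Period:
    kind: str
    duration_s: float
    intensity: float  # µmol photons m⁻² s⁻¹
    colour: str | None = None  # red_655nm / blue_455nm for treatment periods

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"period kind must be one of {_KINDS}")
        if self.duration_s <= 0:
            raise ValueError("period duration must be > 0")
        if self.intensity < 0:
            raise ValueError("period intensity must be >= 0")


@dataclass(frozen=True)
class TreatmentProtocol:
    """Ordered list of light periods; periods are indexed 1-based."""

    periods: tuple[Period, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(self.periods))
        if len(self.periods) < 1:
            raise ValueError("protocol needs at least one period")

    @classmethod
    def standard(cls, growth_light: float, treat_intensity: float,
                 treat_colour: str = "blue_455nm", n_treatment: int = 7,
                 period_s: float = 327.0,
                 recovery_intensity: float = 20.0) -> "TreatmentProtocol":
        """Default light-shift protocol: dark, growth, treatment x n, recovery."""
        periods = [Period("dark", period_s, 0.0),
                   Period("growth", period_s, growth_light)]
        periods += [Period("treatment", period_s, treat_intensity, treat_colour)
                    for _ in range(n_treatment)]
        periods.append(Period("recovery", period_s, recovery_intensity))
        return cls(tuple(periods))

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def total_duration_s(self) -> float:
        return float(sum(p.duration_s for p in self.periods))

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.periods])

    @property
    def durations(self) -> np.ndarray:
        return np.array([p.duration_s for p in self.periods])

    @property
    def kinds(self) -> list[str]:
        return [p.kind for p in self.periods]

    @property
    def t_end_s(self) -> np.ndarray:
        return np.cumsum(self.durations)

    def treatment_indices(self) -> np.ndarray:
        """1-based indices of treatment periods."""
        return np.array([i + 1 for i, p in enumerate(self.periods)
                         if p.kind == "treatment"])


def _per_period_incident_m2(protocol: TreatmentProtocol) -> np.ndarray:
    """Per-period incident dose, photons m⁻²; period 1 excluded by convention."""
    dose = protocol.intensities * protocol.durations * PHOTONS_PER_UMOL
    dose[0] = 0.0
    return dose


def cumulative_incident_photons(protocol: TreatmentProtocol,
                                through_period: int) -> float:
    """Cumulative incident photons m⁻² through 1-based period ``through_period``.

    Sums intensity x duration x 6.022e17 over periods 2..through_period.
    """
    if not 1 <= through_period <= protocol.n_periods:
        raise IndexError("through_period out of range")
    return float(np.sum(_per_period_incident_m2(protocol)[:through_period]))


@dataclass(frozen=True)
class DoseSeries:
    """Per-period and cumulative incident photon doses for a protocol."""

    protocol: TreatmentProtocol
    incident_m2: np.ndarray        # per period, photons m⁻²
    incident_A2: np.ndarray        # per period, quanta Å⁻²
    cumulative_m2: np.ndarray
    cumulative_A2: np.ndarray
    delivered_per_psii: np.ndarray | None = None      # per period
    cumulative_delivered: np.ndarray | None = None
    sigma_psii_2s: np.ndarray | None = None
    _frame_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def with_delivered(self, sigma_psii_2s: np.ndarray) -> "DoseSeries":
        """Attach delivered photons PSII⁻¹ computed from per-period sigma_PSII'2s."""
        sigma = np.asarray(sigma_psii_2s, dtype=float)
        if sigma.shape != self.incident_A2.shape:
            raise ValueError("need one sigma_PSII'2s per period")
        if np.any(sigma < 0):
            raise ValueError("sigma_PSII'2s must be >= 0")
        per = self.incident_A2 * sigma
        return DoseSeries(self.protocol, self.incident_m2, self.incident_A2,
                          self.cumulative_m2, self.cumulative_A2,
                          delivered_per_psii=per,
                          cumulative_delivered=np.cumsum(per),
                          sigma_psii_2s=sigma)

    def to_frame(self) -> pd.DataFrame:
        p = self.protocol
        data = {
            "period": np.arange(1, p.n_periods + 1),
            "kind": p.kinds,
            "t_end_s": p.t_end_s,
            "intensity": p.intensities,
            "incident_m2": self.incident_m2,
            "incident_A2": self.incident_A2,
            "cumulative_incident_m2": self.cumulative_m2,
            "cumulative_incident_A2": self.cumulative_A2,
        }
        if self.delivered_per_psii is not None:
            data["sigma_psii_2s"] = self.sigma_psii_2s
            data["delivered_per_psii"] = self.delivered_per_psii
            data["cumulative_delivered_per_psii"] = self.cumulative_delivered
        return pd.DataFrame(data)


def dose_series(protocol: TreatmentProtocol) -> DoseSeries:
    inc_m2 = _per_period_incident_m2(protocol)
    inc_A2 = inc_m2 / A2_PER_M2
    return DoseSeries(protocol, inc_m2, inc_A2,
                      np.cumsum(inc_m2), np.cumsum(inc_A2))


def delivered_photons_per_psii(ds: DoseSeries,
                               sigma_psii_2s_per_period: np.ndarray) -> np.ndarray:
    """Cumulative photons delivered to PSII photochemistry, photons PSII⁻¹."""
    return ds.with_delivered(sigma_psii_2s_per_period).cumulative_delivered
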
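"""Excitation pressure on PSII from light-state fluorescence levels.

Under actinic light the steady-state fluorescence FS sits between the
open-centre level F0' and the closed-centre level FM'.  Excitation pressure

    1 - qP = 1 - (FM' - FS) / (FM' - F0')

is the fraction of PSII centres closed: 0 when all centres are open and
ready to accept excitation, 1 when all are closed and downstream electron
removal is saturated.  F0' is not measured directly under actinic light; it
is estimated from dark-adapted F0 and FM together with the quenched FM'2s:

    F0' = F0 / ((FM - F0)/FM + F0/FM'2s)

which collapses to F0 when no quenching is present (FM'2s = FM).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["f0_prime", "one_minus_qp", "excitation_pressure_series"]


def f0_prime(f0: float, fm: float, fm_prime_2s: float):
    """Open-centre fluorescence under excitation, from dark F0/FM and FM'2s."""
    f0 = np.asarray(f0, dtype=float)
    fm = np.asarray(fm, dtype=float)
    fm_prime_2s = np.asarray(fm_prime_2s, dtype=float)
    if np.any(f0 <= 0) or np.any(fm_prime_2s <= 0):
        raise ValueError("fluorescence levels must be > 0")
    if np.any(fm <= f0):
        raise ValueError("require FM > F0")
    out = f0 / ((fm - f0) / fm + f0 / fm_prime_2s)
    return float(out) if out.ndim == 0 else out


def one_minus_qp(fs: float, fm_prime: float, f0_prime_: float, clamp: bool = True):
    """Excitation pressure 1 - qP = 1 - (FM' - FS)/(FM' - F0').

    Values outside [0, 1] (measurement noise) are clamped with a warning
    when ``clamp`` is true, otherwise returned as-is.
    """
    fs = np.asarray(fs, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    f0p = np.asarray(f0_prime_, dtype=float)
    if np.any(fm_prime <= f0p):
        raise ValueError("require FM' > F0'")
    val = 1.0 - (fm_prime - fs) / (fm_prime - f0p)
    if clamp and np.any((val < 0) | (val > 1)):
        warnings.warn("1-qP outside [0, 1]; clamping (noisy fluorescence levels)",
                      stacklevel=2)
        val = np.clip(val, 0.0, 1.0)
    return float(val) if val.ndim == 0 else val


def excitation_pressure_series(tc, per_period: bool = False):
    """1-qP for a treatment time course.

    By default returns the value after the first treatment period (the
    series is nearly flat from the first treatment exposure onward); with
    ``per_period`` returns the full per-period vector (NaN where the needed
    levels are absent).
    """
    if tc.fs is None or tc.fm_prime is None or tc.fm_prime_2s is None:
        raise ValueError("time course lacks FS / FM' / FM'2s levels")
    if tc.f0 is None or tc.fm is None:
        raise ValueError("time course lacks dark-adapted F0 and FM")
    f0p = f0_prime(tc.f0, tc.fm, tc.fm_prime_2s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = one_minus_qp(tc.fs, tc.fm_prime, f0p)
    if per_period:
        return series
    treat = tc.protocol.treatment_indices()
    if treat.size == 0:
        raise ValueError("protocol has no treatment period")
    return float(series[treat[0] - 1])
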
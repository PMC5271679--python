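"""Plain-text I/O: induction traces, treatment time courses, result tables.

Time courses and traces are single CSV files with a small ``# key: value``
comment header carrying scalar metadata (species, dark-adapted levels,
train timing), so one file fully reconstructs the in-memory object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import TreatmentTimeCourse
from .dose import Period, TreatmentProtocol
from .induction import FlashletTrain, InductionTrace

__all__ = [
    "write_timecourse", "read_timecourse",
    "write_trace", "read_trace",
    "write_manifest", "read_manifest",
]


def _write_csv(path, meta: dict, frame: pd.DataFrame) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def _read_csv(path) -> tuple[dict, pd.DataFrame]:
    path = Path(path)
    meta = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
    return meta, pd.read_csv(path, skiprows=skip)


def _opt_float(meta: dict, key: str, default=None):
    v = meta.get(key, "")
    if v in ("", "None", "nan"):
        return default
    return float(v)


def write_timecourse(tc: TreatmentTimeCourse, path) -> None:
    meta = {
        "format": "photoinact-timecourse-v1",
        "species": tc.species,
        "growth_light": tc.growth_light,
        "treat_colour": tc.treat_colour,
        "treat_intensity": tc.treat_intensity,
        "f0": tc.f0, "fm": tc.fm,
        "npq_influence_applied": tc.npq_influence_applied,
    }
    if tc.ground_truth:
        meta["ground_truth"] = json.dumps(tc.ground_truth)
    p = tc.protocol
    frame = pd.DataFrame({
        "period": tc.periods,
        "kind": p.kinds,
        "duration_s": p.durations,
        "intensity": p.intensities,
        "colour": [pp.colour or "" for pp in p.periods],
        "elapsed_s": tc.elapsed_s,
        "fs": tc.fs if tc.fs is not None else np.nan,
        "fm_prime": tc.fm_prime if tc.fm_prime is not None else np.nan,
        "f0_prime_2s": tc.f0_prime_2s if tc.f0_prime_2s is not None else np.nan,
        "fm_prime_2s": tc.fm_prime_2s if tc.fm_prime_2s is not None else np.nan,
        "sigma_psii_2s": tc.sigma_psii_2s,
        "fv_fm_2s": tc.fv_fm_2s,
        "fv_fm_2s_ci95": tc.fv_fm_2s_ci95,
    })
    _write_csv(path, meta, frame)


def read_timecourse(path) -> TreatmentTimeCourse:
    meta, df = _read_csv(path)
    if meta.get("format") != "photoinact-timecourse-v1":
        raise ValueError(f"{path}: not a photoinact time-course CSV")
    required = {"period", "kind", "duration_s", "intensity",
                "sigma_psii_2s", "fv_fm_2s", "fv_fm_2s_ci95"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("period")
    periods = tuple(
        Period(kind=r.kind, duration_s=float(r.duration_s),
               intensity=float(r.intensity),
               colour=(r.colour if isinstance(r.colour, str) and r.colour else None))
        for r in df.itertuples())
    gt = json.loads(meta["ground_truth"]) if "ground_truth" in meta else {}

    def col(name):
        if name in df.columns and not df[name].isna().all():
            return df[name].to_numpy(dtype=float)
        return None

    return TreatmentTimeCourse(
        protocol=TreatmentProtocol(periods),
        fv_fm_2s=df["fv_fm_2s"].to_numpy(dtype=float),
        fv_fm_2s_ci95=df["fv_fm_2s_ci95"].to_numpy(dtype=float),
        sigma_psii_2s=df["sigma_psii_2s"].to_numpy(dtype=float),
        f0_prime_2s=col("f0_prime_2s"), fm_prime_2s=col("fm_prime_2s"),
        fs=col("fs"), fm_prime=col("fm_prime"),
        f0=_opt_float(meta, "f0"), fm=_opt_float(meta, "fm"),
        species=meta.get("species", ""),
        growth_light=_opt_float(meta, "growth_light", float("nan")),
        treat_colour=meta.get("treat_colour", ""),
        treat_intensity=_opt_float(meta, "treat_intensity", float("nan")),
        npq_influence_applied=_opt_float(meta, "npq_influence_applied"),
        ground_truth=gt)


def write_trace(trace: InductionTrace, path) -> None:
    t = trace.train
    meta = {
        "format": "photoinact-trace-v1",
        "n_flashlets": t.n_flashlets,
        "flashlet_duration_us": t.flashlet_duration_us,
        "gap_us": t.gap_us,
        "flashlet_dose": t.flashlet_dose,
        "colour": t.colour,
        "context": trace.context,
    }
    frame = pd.DataFrame({
        "flashlet_index": np.arange(t.n_flashlets),
        "time_us": t.time_us,
        "dose_quanta_per_A2": t.doses,
        "fluorescence": trace.fluorescence,
    })
    _write_csv(path, meta, frame)


def read_trace(path) -> InductionTrace:
    meta, df = _read_csv(path)
    if meta.get("format") != "photoinact-trace-v1":
        raise ValueError(f"{path}: not a photoinact trace CSV")
    train = FlashletTrain(
        n_flashlets=int(meta["n_flashlets"]),
        flashlet_duration_us=float(meta["flashlet_duration_us"]),
        gap_us=float(meta["gap_us"]),
        flashlet_dose=float(meta["flashlet_dose"]),
        colour=meta["colour"])
    return InductionTrace(
        train=train,
        fluorescence=df.sort_values("flashlet_index")["fluorescence"].to_numpy(dtype=float),
        context=meta.get("context", "dark_adapted"))


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
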
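"""Synthetic PICU cohort generator.

Emulates the statistical structure the downstream pipeline assumes: a mix of
hemodynamically stable and unstable encounters, age-dependent vitals/labs for
ages 1 month-20 years, realistic per-feature recording frequencies, invasive
vs noninvasive blood-pressure streams, and a pre-intervention physiological
deterioration (rising heart rate and shock index, falling blood pressure,
pH, base excess and urine output) that ramps over the hours before a single
qualifying intervention — a fluid bolus > 10 ml/kg/h or the start of a
vasoactive infusion.

The generator produces the three ingest tables (encounters, chart events,
interventions) as pandas DataFrames and can write them as delimited text
with a provenance header. All randomness flows from one seed; per-patient
sub-streams are split deterministically, so identical (config, seed) pairs
reproduce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    AGE_BIN_EDGES,
    AGE_MAX,
    AGE_MIN,
    DEFAULT_PLAUSIBILITY,
    FEATURE_NAMES,
    VASOACTIVE_DRUGS,
)

__all__ = [
    "SimConfig",
    "ReferenceCurve",
    "reference_value",
    "DEFAULT_CURVES",
    "DEFAULT_RECORDING",
    "DEFAULT_EFFECTS",
    "trajectory",
    "simulate_cohort",
    "write_cohort",
]

_EPOCH = pd.Timestamp("2024-01-01 00:00")

_INVASIVE_BP = ("isbp", "imbp", "idbp")
_NONINVASIVE_BP = ("nsbp", "nmbp", "ndbp")


@dataclass(frozen=True)
class ReferenceCurve:
    """Age-dependent normal range of one feature: piecewise-linear knots.

    ``knots`` are (age_years, mean, sd) triples with strictly increasing ages
    and positive sds; evaluation clamps beyond the end knots.
    """

    feature: str
    knots: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        ages = [k[0] for k in self.knots]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"{self.feature}: knot ages must be strictly increasing")
        if any(k[2] <= 0 for k in self.knots):
            raise ValueError(f"{self.feature}: knot sd must be positive")

    def value(self, age: float) -> tuple[float, float]:
        return reference_value(self, age)


def reference_value(curve: ReferenceCurve, age) -> tuple[float, float]:
    """(mean, sd) of ``curve`` at ``age`` years, piecewise-linear, clamped.

    Negative ages are rejected; ages beyond the knot range clamp to the end
    knots. Accepts scalar or array ages.
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise ValueError("age must be non-negative")
    ages = np.array([k[0] for k in curve.knots])
    means = np.array([k[1] for k in curve.knots])
    sds = np.array([k[2] for k in curve.knots])
    m = np.interp(age_arr, ages, means)
    s = np.interp(age_arr, ages, sds)
    if np.isscalar(age) or age_arr.ndim == 0:
        return float(m), float(s)
    return m, s


def _flat(name: str, mean: float, sd: float) -> ReferenceCurve:
    return ReferenceCurve(name, ((AGE_MIN, mean, sd), (AGE_MAX, mean, sd)))


# Built-in pediatric-plausible normal curves. Age-varying where physiology
# demands it (heart rate, respiratory rate, blood pressures, creatinine,
# weight-normalised urine output); flat otherwise. All configurable.
DEFAULT_CURVES: dict[str, ReferenceCurve] = {
    c.feature: c
    for c in [
        ReferenceCurve(
            "heart_rate",
            ((1 / 12, 140, 15), (1, 120, 15), (3, 105, 14), (6, 95, 13), (12, 80, 12), (20, 70, 11)),
        ),
        ReferenceCurve(
            "respiratory_rate",
            ((1 / 12, 40, 7), (1, 30, 6), (3, 24, 5), (6, 20, 4), (12, 16, 3.5), (20, 14, 3)),
        ),
        ReferenceCurve(
            "nsbp",
            ((1 / 12, 75, 10), (1, 90, 11), (3, 95, 11), (6, 100, 12), (12, 110, 12), (20, 115, 12)),
        ),
        ReferenceCurve(
            "isbp",
            ((1 / 12, 75, 10), (1, 90, 11), (3, 95, 11), (6, 100, 12), (12, 110, 12), (20, 115, 12)),
        ),
        ReferenceCurve(
            "nmbp",
            ((1 / 12, 55, 8), (1, 65, 8), (3, 70, 8), (6, 75, 9), (12, 80, 9), (20, 85, 9)),
        ),
        ReferenceCurve(
            "imbp",
            ((1 / 12, 55, 8), (1, 65, 8), (3, 70, 8), (6, 75, 9), (12, 80, 9), (20, 85, 9)),
        ),
        ReferenceCurve(
            "ndbp",
            ((1 / 12, 40, 7), (1, 50, 7), (3, 53, 7), (6, 57, 7), (12, 62, 8), (20, 65, 8)),
        ),
        ReferenceCurve(
            "idbp",
            ((1 / 12, 40, 7), (1, 50, 7), (3, 53, 7), (6, 57, 7), (12, 62, 8), (20, 65, 8)),
        ),
        ReferenceCurve(
            "creatinine",
            ((1 / 12, 0.3, 0.12), (1, 0.35, 0.12), (3, 0.4, 0.13), (6, 0.5, 0.15), (12, 0.7, 0.18), (20, 0.9, 0.2)),
        ),
        ReferenceCurve(
            "urine_output",
            ((1 / 12, 2.5, 0.7), (1, 2.0, 0.6), (6, 1.5, 0.5), (20, 1.0, 0.4)),
        ),
        _flat("arterial_ph", 7.38, 0.05),
        _flat("bicarbonate", 23.0, 3.0),
        _flat("paco2", 40.0, 6.0),
        _flat("sao2", 96.5, 2.0),
        _flat("base_excess", 0.0, 3.0),
        _flat("pao2", 95.0, 18.0),
        _flat("pf_ratio", 330.0, 80.0),
        _flat("fio2", 0.40, 0.12),
        _flat("mean_airway_pressure", 10.0, 3.0),
        _flat("spo2", 96.5, 2.0),
        _flat("temperature", 37.0, 0.6),
        _flat("glucose", 105.0, 25.0),
        _flat("chloride", 103.0, 4.0),
        _flat("bun", 14.0, 6.0),
        _flat("potassium", 4.2, 0.5),
        _flat("sodium", 139.0, 3.5),
        _flat("alt", 28.0, 14.0),
        _flat("albumin", 4.0, 0.5),
        _flat("total_protein", 6.5, 0.7),
        _flat("wbc", 9.5, 3.5),
        _flat("rbc", 4.5, 0.5),
        _flat("hemoglobin", 12.0, 1.6),
        _flat("platelets", 280.0, 85.0),
        _flat("magnesium", 2.0, 0.25),
        _flat("inr", 1.1, 0.2),
        _flat("lactic_acid", 12.0, 5.0),
    ]
}

# (ever-recorded probability, mean inter-measurement interval in hours).
# Ever-recorded probabilities follow the Table-1-style training-set recording
# percentages; invasive BP is gated by the patient-level arterial-line flag
# instead (its effective rate is SimConfig.p_invasive).
DEFAULT_RECORDING: dict[str, tuple[float, float]] = {
    "arterial_ph": (0.63, 8.0),
    "bicarbonate": (0.63, 8.0),
    "paco2": (0.63, 8.0),
    "sao2": (0.63, 8.0),
    "base_excess": (0.63, 8.0),
    "pao2": (0.63, 8.0),
    "isbp": (1.0, 1.0),  # gated by arterial line (p_invasive)
    "imbp": (1.0, 1.0),
    "idbp": (1.0, 1.0),
    "pf_ratio": (0.41, 8.0),
    "fio2": (0.76, 1.0),
    "mean_airway_pressure": (0.35, 1.0),
    "nsbp": (0.98, 1.0),
    "nmbp": (0.98, 1.0),
    "ndbp": (0.98, 1.0),
    "heart_rate": (1.0, 1.0),
    "respiratory_rate": (0.99, 1.0),
    "spo2": (0.61, 1.0),
    "temperature": (0.99, 4.0),
    "glucose": (0.74, 12.0),
    "chloride": (0.72, 12.0),
    "bun": (0.66, 24.0),
    "creatinine": (0.66, 24.0),
    "potassium": (0.78, 12.0),
    "sodium": (0.77, 12.0),
    "alt": (0.18, 24.0),
    "albumin": (0.18, 24.0),
    "total_protein": (0.18, 24.0),
    "wbc": (0.65, 24.0),
    "rbc": (0.65, 24.0),
    "hemoglobin": (0.68, 24.0),
    "platelets": (0.65, 24.0),
    "magnesium": (0.26, 24.0),
    "inr": (0.37, 24.0),
    "lactic_acid": (0.14, 12.0),
    "urine_output": (0.77, 4.0),
}

# Standardized drift (in reference-curve SDs) reached at intervention onset,
# signed in the direction of decompensating shock: tachycardia, hypotension,
# acidosis with falling base excess, rising lactate, oliguria, escalating
# respiratory support.
DEFAULT_EFFECTS: dict[str, float] = {
    "heart_rate": +2.0,
    "nsbp": -0.8,
    "isbp": -0.8,
    "nmbp": -0.6,
    "imbp": -0.6,
    "ndbp": -0.6,
    "idbp": -0.6,
    "arterial_ph": -1.5,
    "base_excess": -1.5,
    "bicarbonate": -1.0,
    "lactic_acid": +2.0,
    "urine_output": -1.5,
    "respiratory_rate": +1.0,
    "temperature": +0.5,
    "pao2": -0.5,
    "spo2": -0.5,
    "sao2": -0.5,
    "pf_ratio": -0.8,
    "mean_airway_pressure": +1.0,
    "fio2": +1.0,
    "inr": +0.5,
    "bun": +0.5,
    "creatinine": +0.5,
    "glucose": +0.5,
    "albumin": -0.5,
    "platelets": -0.5,
    "wbc": +0.5,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults reflect the target population: 42% instability prevalence,
    uniform weights over the five pediatric age strata, a 70/30 fluid-bolus /
    vasoactive intervention mix, and an arterial line in half the patients.
    """

    n_patients: int = 100
    unstable_fraction: float = 0.42
    age_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    recording_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RECORDING)
    )
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    # Pre-intervention drift ramps over the 24 h before onset, so the signal
    # spans the whole 1-12 h lead-time evaluation range (the modelled system
    # shows clearly above-chance discrimination a full 12 h out).
    deterioration_duration: float = 24.0
    noise_sd_scale: float = 1.0
    p_invasive: float = 0.5
    fluid_fraction: float = 0.7  # share of interventions that are fluid boluses
    gross_error_rate: float = 0.001  # implausible charting errors, exercises the filter
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.unstable_fraction <= 1.0:
            raise ValueError("unstable_fraction must be in [0, 1]")
        for p in (self.p_invasive, self.fluid_fraction, self.gross_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for name, (p_ever, interval) in self.recording_rates.items():
            if not 0.0 <= p_ever <= 1.0:
                raise ValueError(f"recording rate for {name} must be in [0, 1]")
            if interval <= 0:
                raise ValueError(f"interval for {name} must be positive")
        if self.deterioration_duration <= 0:
            raise ValueError("deterioration_duration must be positive")
        if len(self.age_weights) != len(AGE_BIN_EDGES) - 1 or min(self.age_weights) < 0:
            raise ValueError("age_weights must be 5 non-negative weights")
        if self.noise_sd_scale < 0:
            raise ValueError("noise_sd_scale must be non-negative")

    def digest(self) -> str:
        payload = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _patient_rng(config: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


def _stratified_age(rng: np.random.Generator, weights) -> float:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    stratum = rng.choice(len(w), p=w)
    lo, hi = AGE_BIN_EDGES[stratum], AGE_BIN_EDGES[stratum + 1]
    return float(rng.uniform(lo, hi))


def trajectory(
    encounter: dict,
    onset: pd.Timestamp | None,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Chart events for one encounter, with a pre-onset deterioration ramp.

    For an unstable encounter (``onset`` given), each feature's mean shifts
    monotonically toward its shock direction over the ``deterioration_duration``
    hours ending at onset, scaled by the configured effect size; the drift is
    held at its full value after onset (no therapy-response modelling).
    Stable encounters (``onset=None``) sample their baseline throughout.
    """
    admission = pd.Timestamp(encounter["admission_time"])
    discharge = pd.Timestamp(encounter["discharge_time"])
    age = float(encounter["age_years"])
    invasive = bool(encounter.get("invasive", False))
    if onset is not None:
        onset = pd.Timestamp(onset)
        if onset < admission + pd.Timedelta(hours=6):
            raise ValueError("onset must be at least 6 h after admission")
        if onset > discharge:
            raise ValueError("onset must fall within the stay")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    los_h = (discharge - admission).total_seconds() / 3600.0
    onset_h = None if onset is None else (onset - admission).total_seconds() / 3600.0
    ramp_h = config.deterioration_duration

    t_parts: list[np.ndarray] = []
    v_parts: list[np.ndarray] = []
    f_parts: list[np.ndarray] = []
    s_parts: list[np.ndarray] = []
    for feat in FEATURE_NAMES:
        p_ever, interval = config.recording_rates[feat]
        if feat in _INVASIVE_BP:
            if not invasive:
                continue
        elif rng.random() >= p_ever:
            continue
        # Poisson measurement process with mean gap = interval
        n_max = max(4, int(los_h / interval * 3) + 8)
        gaps = rng.exponential(interval, size=n_max)
        t = np.cumsum(gaps) + rng.uniform(0, interval)
        t = t[t < los_h]
        if t.size == 0:
            continue
        mean, sd = reference_value(DEFAULT_CURVES[feat], age)
        sd_eff = sd * config.noise_sd_scale
        values = mean + rng.normal(0.0, 1.0, size=t.size) * sd_eff
        if onset_h is not None:
            effect = config.effect_sizes.get(feat, 0.0)
            if effect:
                ramp = np.clip((t - (onset_h - ramp_h)) / ramp_h, 0.0, 1.0)
                values = values + effect * sd * ramp
        # physiologic clipping so simulated values stay mostly plausible
        if feat == "fio2":
            values = np.clip(values, 0.21, 1.0)
        elif feat in ("spo2", "sao2"):
            values = np.clip(values, 40.0, 100.0)
        elif feat == "urine_output":
            values = np.clip(values, 0.0, None)
        elif feat in ("lactic_acid", "inr", "creatinine", "bun", "alt"):
            lo = DEFAULT_PLAUSIBILITY[feat][0]
            values = np.clip(values, lo, None)
        # rare gross charting errors (land outside the plausibility range)
        if config.gross_error_rate > 0:
            bad = rng.random(t.size) < config.gross_error_rate
            if bad.any():
                values = values.copy()
                values[bad] = DEFAULT_PLAUSIBILITY[feat][1] * 2.0 + 10.0
        source = (
            "invasive"
            if feat in _INVASIVE_BP
            else ("noninvasive" if feat in _NONINVASIVE_BP else "n/a")
        )
        t_parts.append(t)
        v_parts.append(values)
        f_parts.append(np.full(t.size, feat, dtype=object))
        s_parts.append(np.full(t.size, source, dtype=object))
    if not t_parts:
        return pd.DataFrame(columns=["encounter_id", "time", "feature", "value", "source"])
    hours = np.concatenate(t_parts)
    times = (admission + pd.to_timedelta(hours, unit="h")).floor("min")
    out = pd.DataFrame(
        {
            "encounter_id": encounter["encounter_id"],
            "time": times,
            "feature": np.concatenate(f_parts),
            "value": np.concatenate(v_parts),
            "source": np.concatenate(s_parts),
        }
    )
    return out.sort_values(["time", "feature"], kind="mergesort").reset_index(drop=True)


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (encounters, chart events, interventions).

    Exactly ``round(unstable_fraction * n_patients)`` patients receive one
    qualifying intervention each, always later than 6 h after admission.
    Output tables conform to the ingest schema.
    """
    n = config.n_patients
    n_unstable = int(round(config.unstable_fraction * n))
    if config.unstable_fraction > 0 and n_unstable < 1:
        warnings.warn("unstable_fraction * n_patients < 1; generating an all-stable cohort")
        n_unstable = 0

    enc_rows, chart_frames, iv_rows = [], [], []
    drug_list = sorted(VASOACTIVE_DRUGS)
    for i in range(n):
        rng = _patient_rng(config, i)
        unstable = i < n_unstable
        age = _stratified_age(rng, config.age_weights)
        admission = (_EPOCH + pd.Timedelta(hours=3 * i)).floor("min")
        if unstable:
            los_h = float(np.clip(rng.lognormal(np.log(10 * 24), 0.6), 36.0, 60 * 24))
        else:
            los_h = float(np.clip(rng.lognormal(np.log(2.7 * 24), 0.8), 10.0, 30 * 24))
        discharge = (admission + pd.Timedelta(hours=los_h)).floor("min")
        invasive = rng.random() < config.p_invasive
        ventilated = rng.random() < (0.561 if unstable else 0.285)
        died = rng.random() < (0.06 if unstable else 0.011)
        enc = {
            "encounter_id": f"e{i:05d}",
            "patient_id": f"p{i:05d}",
            "admission_time": admission,
            "discharge_time": discharge,
            "age_years": round(age, 4),
            "ventilated": ventilated,
            "died": died,
            "invasive": invasive,
        }
        onset = None
        if unstable:
            onset_h = float(rng.uniform(8.0, min(los_h - 4.0, 120.0)))
            onset = (admission + pd.Timedelta(hours=onset_h)).floor("min")
            if rng.random() < config.fluid_fraction:
                iv_rows.append(
                    {
                        "encounter_id": enc["encounter_id"],
                        "time": onset,
                        "kind": "fluid_bolus",
                        "rate_ml_kg_h": round(float(rng.uniform(11.0, 40.0)), 1),
                        "drug": "",
                    }
                )
            else:
                iv_rows.append(
                    {
                        "encounter_id": enc["encounter_id"],
                        "time": onset,
                        "kind": "vasoactive",
                        "rate_ml_kg_h": np.nan,
                        "drug": drug_list[rng.integers(len(drug_list))],
                    }
                )
        chart_frames.append(trajectory(enc, onset, config, rng))
        enc_rows.append(enc)

    encounters = pd.DataFrame(enc_rows).drop(columns=["invasive"])
    chart = (
        pd.concat(chart_frames, ignore_index=True)
        if chart_frames
        else pd.DataFrame(columns=["encounter_id", "time", "feature", "value", "source"])
    )
    interventions = pd.DataFrame(
        iv_rows, columns=["encounter_id", "time", "kind", "rate_ml_kg_h", "drug"]
    )
    return encounters, chart, interventions


def write_cohort(
    tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    outdir: str | Path,
    config: SimConfig,
) -> dict[str, Path]:
    """Write the three ingest tables as CSV with a provenance header line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# hiikit-sim seed={config.seed} config_sha={config.digest()}\n"
    names = ("encounters", "chart", "interventions")
    paths = {}
    for name, df in zip(names, tables):
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        paths[name] = path
    return paths
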
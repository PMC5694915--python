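"""Windowed feature extraction and intervention-based labeling.

An encounter is *unstable* if the patient received a qualifying hemodynamic
intervention — a fluid bolus > 10 ml/kg/h or the start of a vasoactive
infusion (dopamine, dobutamine, epinephrine, norepinephrine, neosynephrine
or vasopressin) — and *stable* if no such intervention occurred during the
stay. The onset is the time of the first qualifying intervention. Features
are the last charted value of each variable within the 24-hour observation
window ending at the reference time; variables never measured in the window
are missing. Patients unstable within 6 h of admission are excluded, as are
repeat admissions: only each patient's first admission counts.

Composite indices (shock index, oxygenation index, oxygen-saturation index)
are derived after extraction, with invasive systolic/mean pressures
preferred over cuff values when both are present.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .features import (
    AGE_MAX,
    AGE_MIN,
    COMPOSITES,
    FEATURE_NAMES,
    FLUID_RATE_THRESHOLD,
    MODEL_FEATURES,
    VASOACTIVE_DRUGS,
)

__all__ = [
    "derive_composites",
    "extract_window",
    "find_onset",
    "label_cohort",
    "split_dataset",
    "to_matrix",
]

log = logging.getLogger("hiikit.labeling")

_META_COLS = ["encounter_id", "patient_id", "label", "reference_time", "onset_time", "lead_time", "age"]


def derive_composites(frame: pd.DataFrame) -> pd.DataFrame:
    """Add shock index, OI and OSI columns to a feature frame.

    SI = HR / SBP with invasive SBP preferred over the cuff value; OI and
    OSI use mean airway pressure (cmH2O) and FiO2 as a fraction. A composite
    is missing whenever any constituent is missing, or when its denominator
    is zero (logged division guard).
    """
    out = frame.copy()
    sbp = out["isbp"].where(out["isbp"].notna(), out.get("nsbp"))
    mbp_air = out["mean_airway_pressure"]
    with np.errstate(divide="ignore", invalid="ignore"):
        si = out["heart_rate"] / sbp
        oi = mbp_air * out["fio2"] * 100.0 / out["pao2"]
        osi = mbp_air * out["fio2"] * 100.0 / out["spo2"]
    zeros = int((sbp == 0).sum() + (out["pao2"] == 0).sum() + (out["spo2"] == 0).sum())
    if zeros:
        log.warning("composite division guard tripped on %d zero denominators", zeros)
    out["si"] = si.where(np.isfinite(si))
    out["oi"] = oi.where(np.isfinite(oi))
    out["osi"] = osi.where(np.isfinite(osi))
    return out


def _last_in_window(
    events: pd.DataFrame, refs: pd.DataFrame, window_h: float
) -> pd.DataFrame:
    """Last value per (encounter, feature) in (ref - window, ref]; wide layout.

    ``refs`` needs columns encounter_id, reference_time; its row order is
    preserved in the output (one row per ref row).
    """
    refs = refs.reset_index(drop=True)
    merged = events.merge(
        refs.assign(_row=np.arange(len(refs)))[["encounter_id", "reference_time", "_row"]],
        on="encounter_id",
        how="inner",
    )
    lo = merged["reference_time"] - pd.Timedelta(hours=window_h)
    keep = (merged["time"] > lo) & (merged["time"] <= merged["reference_time"])
    merged = merged.loc[keep]
    merged = merged.sort_values("time", kind="mergesort")
    last = merged.groupby(["_row", "feature"], sort=False)["value"].last().unstack()
    wide = last.reindex(index=np.arange(len(refs)), columns=list(FEATURE_NAMES))
    wide.index.name = None
    return wide


def extract_window(
    events: pd.DataFrame,
    reference_time: pd.Timestamp,
    age: float,
    window_h: float = 24.0,
    admission_time: pd.Timestamp | None = None,
    discharge_time: pd.Timestamp | None = None,
) -> pd.Series:
    """Feature vector for one encounter at ``reference_time``.

    The last measurement of each variable within the half-open window
    (reference_time - window, reference_time] is used; composites are
    derived afterward. Returns a Series over the model features plus age.
    """
    reference_time = pd.Timestamp(reference_time)
    if admission_time is not None and reference_time < pd.Timestamp(admission_time):
        raise ValueError("reference_time precedes admission")
    if discharge_time is not None and reference_time > pd.Timestamp(discharge_time):
        raise ValueError("reference_time is after discharge")
    refs = pd.DataFrame(
        {"encounter_id": events["encounter_id"].iloc[:1].tolist() or ["_"], "reference_time": [reference_time]}
    )
    if events.empty:
        wide = pd.DataFrame(np.nan, index=[0], columns=list(FEATURE_NAMES))
    else:
        refs["encounter_id"] = events["encounter_id"].iloc[0]
        wide = _last_in_window(events, refs, window_h)
    wide = derive_composites(wide)
    vec = wide.iloc[0].copy()
    vec["age"] = float(age)
    return vec


def find_onset(
    interventions: pd.DataFrame,
    fluid_threshold: float = FLUID_RATE_THRESHOLD,
    vasoactive_drugs: frozenset[str] = VASOACTIVE_DRUGS,
) -> pd.Timestamp | None:
    """Time of the first qualifying intervention for one encounter, or None.

    A fluid bolus qualifies only at a rate strictly greater than
    ``fluid_threshold`` ml/kg/h; a vasoactive event qualifies only for a drug
    in the accepted list.
    """
    if interventions.empty:
        return None
    fluid = (interventions["kind"] == "fluid_bolus") & (
        interventions["rate_ml_kg_h"] > fluid_threshold
    )
    vaso = (interventions["kind"] == "vasoactive") & interventions["drug"].isin(
        vasoactive_drugs
    )
    qualifying = interventions.loc[fluid | vaso, "time"]
    if qualifying.empty:
        return None
    return qualifying.min()


def _qualifying_onsets(interventions, fluid_threshold, vasoactive_drugs) -> pd.Series:
    """encounter_id -> earliest qualifying intervention time."""
    if interventions.empty:
        return pd.Series(dtype="datetime64[ns]")
    fluid = (interventions["kind"] == "fluid_bolus") & (
        interventions["rate_ml_kg_h"] > fluid_threshold
    )
    vaso = (interventions["kind"] == "vasoactive") & interventions["drug"].isin(
        vasoactive_drugs
    )
    q = interventions.loc[fluid | vaso]
    return q.groupby("encounter_id")["time"].min()


def label_cohort(
    encounters: pd.DataFrame,
    events: pd.DataFrame,
    interventions: pd.DataFrame,
    control_seed: int = 0,
    lead_times: tuple[float, ...] = (),
    window_h: float = 24.0,
    fluid_threshold: float = FLUID_RATE_THRESHOLD,
    vasoactive_drugs: frozenset[str] = VASOACTIVE_DRUGS,
    exclusions: tuple[str, ...] = (
        "not_first_admission",
        "early_instability",
        "no_charted_data",
        "age_out_of_range",
    ),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every encounter and extract windowed feature vectors.

    Unstable encounters get reference_time = onset (lead_time 0) plus one
    extra vector per requested lead time L at onset - L hours; stable
    encounters get a seeded random reference time within the stay. Returns
    (examples, exclusion ledger); excluded-encounter counts plus labeled
    encounters add up to the input encounter count.
    """
    ledger = {k: 0 for k in exclusions}
    enc = encounters.copy()

    if "not_first_admission" in exclusions and len(enc):
        first = enc.sort_values("admission_time", kind="mergesort").groupby("patient_id").head(1)
        dropped = len(enc) - len(first)
        ledger["not_first_admission"] = int(dropped)
        enc = first
    if "age_out_of_range" in exclusions and len(enc):
        ok = (enc["age_years"] >= AGE_MIN) & (enc["age_years"] <= AGE_MAX)
        ledger["age_out_of_range"] = int((~ok).sum())
        enc = enc.loc[ok]
    if "no_charted_data" in exclusions and len(enc):
        charted = set(events["encounter_id"].unique())
        ok = enc["encounter_id"].isin(charted)
        ledger["no_charted_data"] = int((~ok).sum())
        enc = enc.loc[ok]

    onsets = _qualifying_onsets(interventions, fluid_threshold, vasoactive_drugs)
    enc = enc.assign(onset_time=enc["encounter_id"].map(onsets))
    if "early_instability" in exclusions and len(enc):
        early = enc["onset_time"].notna() & (
            enc["onset_time"] < enc["admission_time"] + pd.Timedelta(hours=6)
        )
        ledger["early_instability"] = int(early.sum())
        enc = enc.loc[~early]
    enc = enc.reset_index(drop=True)

    rng = np.random.default_rng(control_seed)
    refs_rows = []
    for _, row in enc.iterrows():
        if pd.notna(row["onset_time"]):
            base_ref = row["onset_time"]
            refs_rows.append((row, "unstable", base_ref, 0.0))
            for L in lead_times:
                refs_rows.append((row, "unstable", row["onset_time"] - pd.Timedelta(hours=L), float(L)))
        else:
            # control window: prefer a reference with a full 24 h of history
            lo = row["admission_time"] + pd.Timedelta(hours=window_h)
            if lo >= row["discharge_time"]:
                lo = row["admission_time"] + pd.Timedelta(hours=6)
            if lo >= row["discharge_time"]:
                lo = row["discharge_time"]
            span_s = (row["discharge_time"] - lo).total_seconds()
            ref = lo + pd.Timedelta(seconds=float(rng.uniform(0, max(span_s, 0))))
            refs_rows.append((row, "stable", ref.floor("min"), np.nan))

    if not refs_rows:
        empty = pd.DataFrame(columns=_META_COLS + list(MODEL_FEATURES))
        return empty, ledger

    refs = pd.DataFrame(
        {
            "encounter_id": [r[0]["encounter_id"] for r in refs_rows],
            "patient_id": [r[0]["patient_id"] for r in refs_rows],
            "label": [r[1] for r in refs_rows],
            "reference_time": [r[2] for r in refs_rows],
            "onset_time": [r[0]["onset_time"] for r in refs_rows],
            "lead_time": [r[3] for r in refs_rows],
            "age": [float(r[0]["age_years"]) for r in refs_rows],
        }
    )
    wide = _last_in_window(events, refs, window_h)
    wide = derive_composites(wide)
    examples = pd.concat([refs, wide[list(MODEL_FEATURES)]], axis=1)

    # label-leakage guard: no unstable window may extend past its onset
    unstable = examples["label"] == "unstable"
    assert (examples.loc[unstable, "reference_time"] <= examples.loc[unstable, "onset_time"]).all()
    return examples, ledger


def split_dataset(
    examples: pd.DataFrame,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level, label-stratified train/test split of base examples.

    Only lead_time-0/NaN rows define patient membership; all of a patient's
    rows land on one side. Raises if either class is absent.
    """
    base = examples[examples["lead_time"].fillna(0.0) == 0.0]
    patients = base.groupby("patient_id")["label"].first()
    if set(patients.unique()) != {"stable", "unstable"}:
        raise ValueError("both classes must be present to split")
    if len(patients) < 10:
        raise ValueError("need at least 10 examples to split")
    rng = np.random.default_rng(seed)
    test_patients: list[str] = []
    for lab in ("stable", "unstable"):
        ids = np.array(sorted(patients.index[patients == lab]))
        rng.shuffle(ids)
        n_test = int(round(len(ids) * (1.0 - train_fraction)))
        test_patients.extend(ids[:n_test])
    if not test_patients:
        warnings.warn("train_fraction leaves an empty test set")
    is_test = examples["patient_id"].isin(set(test_patients))
    return examples.loc[~is_test].reset_index(drop=True), examples.loc[is_test].reset_index(drop=True)


def to_matrix(examples: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """(X, y, age) for the learner: X over model features, y in {+1, -1}."""
    X = examples[list(MODEL_FEATURES)].astype(float)
    y = np.where(examples["label"].to_numpy() == "unstable", 1, -1)
    age = examples["age"].to_numpy(dtype=float)
    return X, y, age


def export_matrix(examples: pd.DataFrame, path, na_token: str = "NA") -> None:
    """Write labeled examples as a delimited feature matrix with explicit NAs."""
    examples.to_csv(path, index=False, na_rep=na_token)
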
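"""Reading and cleaning of raw clinical tables.

Three delimited text tables feed the pipeline: encounters, chart events and
interventions. Cleaning enforces a per-feature physiologic plausibility
range (out-of-range values become missing), reconciles paired invasive /
noninvasive blood-pressure streams (a cuff reading within the proximity
window of an arterial-line reading of the same component is discarded), and
applies measurement-staleness rules at scoring time (blood pressure and
ventilator parameters expire after 1 hour, laboratory values and other
vitals after 24 hours).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .features import (
    BP_COMPONENT_PAIRS,
    DEFAULT_PLAUSIBILITY,
    FEATURE_NAMES,
    canonical_name,
    staleness_hours,
)

__all__ = [
    "read_tables",
    "load_alias_map",
    "plausibility_filter",
    "reconcile_bp",
    "staleness_gate",
]

log = logging.getLogger("hiikit.ingest")

_ENC_COLS = [
    "encounter_id",
    "patient_id",
    "admission_time",
    "discharge_time",
    "age_years",
    "ventilated",
    "died",
]
_CHART_COLS = ["encounter_id", "time", "feature", "value", "source"]
_IV_COLS = ["encounter_id", "time", "kind", "rate_ml_kg_h", "drug"]


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Read a feature-synonym map (YAML: raw name -> canonical name)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("alias map must be a mapping of synonym -> canonical name")
    bad = sorted(v for v in data.values() if v not in FEATURE_NAMES)
    if bad:
        raise ValueError(f"alias map targets unknown features: {bad}")
    return {str(k).strip().lower().replace(" ", "_"): v for k, v in data.items()}


def _read_csv(path: str | Path, required: list[str], sep: str | None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_tables(
    encounters_path: str | Path,
    chart_path: str | Path,
    interventions_path: str | Path,
    aliases: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Read and type the three raw tables.

    Feature labels are canonicalized through the alias map; rows with unknown
    features or unparseable values/timestamps are dropped and counted. Lines
    beginning ``#`` are provenance comments. ``sep=None`` sniffs comma/tab.

    Returns (encounters, chart, interventions, drop_counts).
    """
    drops: dict[str, int] = {}

    enc = _read_csv(encounters_path, _ENC_COLS, sep)
    for col in ("admission_time", "discharge_time"):
        enc[col] = pd.to_datetime(enc[col], errors="coerce").dt.floor("min")
    enc["age_years"] = pd.to_numeric(enc["age_years"], errors="coerce")
    bad = enc[["admission_time", "discharge_time", "age_years"]].isna().any(axis=1)
    bad |= enc["discharge_time"] <= enc["admission_time"]
    drops["encounters_unparseable"] = int(bad.sum())
    enc = enc.loc[~bad].reset_index(drop=True)
    for col in ("ventilated", "died"):
        enc[col] = enc[col].astype(str).str.strip().str.lower().isin(("true", "1", "yes", "y"))

    chart = _read_csv(chart_path, _CHART_COLS, sep)
    chart["time"] = pd.to_datetime(chart["time"], errors="coerce").dt.floor("min")
    chart["value"] = pd.to_numeric(chart["value"], errors="coerce")
    canon = chart["feature"].astype(str).map(lambda s: canonical_name(s, aliases))
    unknown = canon.isna()
    if unknown.any():
        for name in sorted(chart.loc[unknown, "feature"].astype(str).str.strip().unique()):
            log.warning("dropping rows with unknown feature name: %r", name)
    drops["chart_unknown_feature"] = int(unknown.sum())
    bad = chart["time"].isna() | chart["value"].isna()
    drops["chart_unparseable"] = int((bad & ~unknown).sum())
    chart = chart.loc[~(bad | unknown)].reset_index(drop=True)
    chart["feature"] = canon.loc[chart.index]
    chart["source"] = chart["source"].fillna("n/a").astype(str).str.strip().str.lower()
    # FiO2 arrives as a percentage in many flowsheets; store as a fraction
    pct = (chart["feature"] == "fio2") & (chart["value"] > 1.0)
    chart.loc[pct, "value"] = chart.loc[pct, "value"] / 100.0
    chart = chart.sort_values(["encounter_id", "time"], kind="mergesort").reset_index(drop=True)

    iv = _read_csv(interventions_path, _IV_COLS, sep)
    iv["time"] = pd.to_datetime(iv["time"], errors="coerce").dt.floor("min")
    iv["rate_ml_kg_h"] = pd.to_numeric(iv["rate_ml_kg_h"], errors="coerce")
    iv["kind"] = iv["kind"].astype(str).str.strip().str.lower()
    iv["drug"] = iv["drug"].fillna("").astype(str).str.strip().str.lower()
    bad = iv["time"].isna() | ~iv["kind"].isin(("fluid_bolus", "vasoactive"))
    bad |= (iv["kind"] == "fluid_bolus") & iv["rate_ml_kg_h"].isna()
    drops["interventions_unparseable"] = int(bad.sum())
    iv = iv.loc[~bad].reset_index(drop=True)

    if any(drops.values()):
        log.info("ingest drop counts: %s", {k: v for k, v in drops.items() if v})
    return enc, chart, iv, drops


def plausibility_filter(
    chart: pd.DataFrame,
    table: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove chart events outside the physiologically valid range.

    Removal means the value is later treated as missing. The plausibility
    table must cover every feature present. Idempotent. Returns the filtered
    events and per-feature removal counts.
    """
    table = DEFAULT_PLAUSIBILITY if table is None else table
    present = set(chart["feature"].unique())
    uncovered = sorted(present - set(table))
    if uncovered:
        raise KeyError(f"plausibility table missing feature(s): {uncovered}")
    lo = chart["feature"].map({k: v[0] for k, v in table.items()})
    hi = chart["feature"].map({k: v[1] for k, v in table.items()})
    ok = (chart["value"] >= lo) & (chart["value"] <= hi)
    removed = chart.loc[~ok, "feature"].value_counts().to_dict()
    return chart.loc[ok].reset_index(drop=True), {k: int(v) for k, v in removed.items()}


def reconcile_bp(chart: pd.DataFrame, proximity_min: float = 20.0) -> pd.DataFrame:
    """Drop cuff BP readings taken close to an arterial-line reading.

    For each noninvasive systolic/mean/diastolic event with an invasive event
    of the same component in the same encounter within ``proximity_min``
    minutes, the noninvasive event is removed; invasive events are always
    retained. Idempotent; a no-op when either source is absent.
    """
    if chart.empty:
        return chart
    drop_mask = pd.Series(False, index=chart.index)
    tol = pd.Timedelta(minutes=proximity_min)
    for n_feat, i_feat in BP_COMPONENT_PAIRS.items():
        noninv = chart[chart["feature"] == n_feat]
        inv = chart[chart["feature"] == i_feat]
        if noninv.empty or inv.empty:
            continue
        left = noninv[["encounter_id", "time"]].reset_index()
        right = (
            inv[["encounter_id", "time"]]
            .rename(columns={"time": "inv_time"})
            .sort_values("inv_time", kind="mergesort")
        )
        merged = pd.merge_asof(
            left.sort_values("time", kind="mergesort"),
            right,
            left_on="time",
            right_on="inv_time",
            by="encounter_id",
            direction="nearest",
            tolerance=tol,
        )
        hit = merged.loc[merged["inv_time"].notna(), "index"]
        drop_mask.loc[hit] = True
    return chart.loc[~drop_mask].reset_index(drop=True)


def staleness_gate(
    events: pd.DataFrame,
    now: pd.Timestamp,
    admission_time: pd.Timestamp | None = None,
    horizons: dict[str, float] | None = None,
) -> dict[str, float]:
    """Most recent non-stale value per feature for one encounter at ``now``.

    A feature contributes its latest value whose age is within the feature's
    staleness horizon; otherwise it is missing (absent from the returned
    map). Only events at or before ``now`` are consulted — no lookahead.
    """
    now = pd.Timestamp(now)
    if admission_time is not None and now < pd.Timestamp(admission_time):
        raise ValueError("now precedes admission")
    past = events[events["time"] <= now].sort_values("time", kind="mergesort")
    if past.empty:
        return {}
    last = past.groupby("feature", sort=False).tail(1)
    out: dict[str, float] = {}
    for _, row in last.iterrows():
        horizon = pd.Timedelta(hours=staleness_hours(row["feature"], horizons))
        if now - row["time"] <= horizon:
            out[row["feature"]] = float(row["value"])
    return out
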
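"""Streaming HII scorer: events in, risk time series out.

At a configurable cadence the scorer gates the event stream through the
staleness rules (blood pressure / ventilator values expire after 1 h, labs
and other vitals after 24 h), derives the composite indices, and maps the
ensemble margin to the hemodynamic instability indicator (HII), a 0-1
probability. The probability is banded into three colors — green (low),
yellow (medium), red (high risk). Heart rate and age are the minimum inputs;
ticks without them emit an explicit no-output marker. Scoring is strictly
causal: no event after a tick can influence it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boosting import BoostModel
from .features import FEATURE_NAMES
from .ingest import staleness_gate
from .labeling import derive_composites

__all__ = ["risk_color", "default_bands", "score_stream", "explain"]


def risk_color(p: float, bands: tuple[float, float]) -> str:
    """Map an HII probability to green / yellow / red.

    ``bands = (c1, c2)`` with 0 < c1 < c2 < 1; green below c1, yellow in
    [c1, c2), red at or above c2 (lower bounds closed).
    """
    c1, c2 = bands
    if not (0.0 < c1 < c2 < 1.0):
        raise ValueError("bands must satisfy 0 < c1 < c2 < 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    if p < c1:
        return "green"
    if p < c2:
        return "yellow"
    return "red"


def default_bands(model: BoostModel) -> tuple[float, float]:
    """Color cutpoints: red at the model's operating threshold, yellow 0.1 below."""
    c2 = model.operating_threshold if model.operating_threshold is not None else 0.5
    c2 = min(max(c2, 1e-6), 1.0 - 1e-6)  # saturated thresholds stay inside (0, 1)
    c1 = max(c2 - 0.1, c2 / 2.0)
    return (c1, c2)


def explain(model: BoostModel, vector: pd.Series) -> pd.DataFrame:
    """Ranked per-feature contributions to the margin of one vector.

    Features whose stumps all abstained are flagged ``missing`` rather than
    reported as zero; voted contributions sum exactly to the margin.
    """
    contribs = model.contributions(vector)
    rows = []
    model_feats = {s.feature for s in model.stumps}
    for feat in model_feats:
        if feat in contribs:
            rows.append({"feature": feat, "contribution": contribs[feat], "status": "voted"})
        else:
            rows.append({"feature": feat, "contribution": np.nan, "status": "missing"})
    out = pd.DataFrame(rows, columns=["feature", "contribution", "status"])
    return out.sort_values(
        "contribution", key=lambda s: -s.abs().fillna(-1.0), kind="mergesort"
    ).reset_index(drop=True)


def score_stream(
    model: BoostModel,
    events: pd.DataFrame,
    age: float,
    cadence_min: float = 1.0,
    bands: tuple[float, float] | None = None,
    start: pd.Timestamp | None = None,
    end: pd.Timestamp | None = None,
    top_k: int = 3,
) -> pd.DataFrame:
    """Score one encounter's event stream on a regular cadence.

    Returns a row per tick: ``time, hii, color, margin, top_contributors,
    reason``. Ticks where the minimum inputs (heart rate + age) are missing
    carry ``hii = NaN`` and a reason instead of a silent skip.
    """
    if events.empty:
        return pd.DataFrame(columns=["time", "hii", "color", "margin", "top_contributors", "reason"])
    if not events["time"].is_monotonic_increasing:
        raise ValueError("event stream must be time-sorted")
    if bands is None:
        bands = default_bands(model)
    start = events["time"].iloc[0] if start is None else pd.Timestamp(start)
    end = events["time"].iloc[-1] if end is None else pd.Timestamp(end)
    ticks = pd.date_range(start, end, freq=pd.Timedelta(minutes=cadence_min))

    rows = []
    for now in ticks:
        current = staleness_gate(events, now, horizons=model.staleness)
        if "heart_rate" not in current or pd.isna(age):
            rows.append(
                {
                    "time": now,
                    "hii": np.nan,
                    "color": "",
                    "margin": np.nan,
                    "top_contributors": "",
                    "reason": "insufficient inputs (heart rate + age required)",
                }
            )
            continue
        vec = pd.Series({f: current.get(f, np.nan) for f in FEATURE_NAMES}, dtype=float)
        vec = derive_composites(vec.to_frame().T).iloc[0]
        vec["age"] = age
        try:
            m = model.margin(vec) if model.stumps else 0.0
        except ValueError:  # every stump abstained on the gated snapshot
            rows.append(
                {
                    "time": now,
                    "hii": np.nan,
                    "color": "",
                    "margin": np.nan,
                    "top_contributors": "",
                    "reason": "insufficient inputs (all weak classifiers abstained)",
                }
            )
            continue
        hii = 1.0 / (1.0 + np.exp(-2.0 * m))
        contribs = sorted(
            model.contributions(vec).items(), key=lambda kv: -abs(kv[1])
        )[:top_k]
        rows.append(
            {
                "time": now,
                "hii": hii,
                "color": risk_color(hii, bands),
                "margin": m,
                "top_contributors": ";".join(f"{f}={c:+.3f}" for f, c in contribs),
                "reason": "",
            }
        )
    return pd.DataFrame(rows)
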
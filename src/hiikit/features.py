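"""Canonical feature catalogue for the hemodynamic-instability pipeline.

The model consumes 36 charted clinical variables (vital signs, laboratory
values and ventilator parameters) plus patient age, and three composite
indices derived from them:

* shock index        SI  = HR / SBP          (invasive SBP preferred)
* oxygenation index  OI  = MAP * FiO2 * 100 / PaO2
* oxygen-saturation index OSI = MAP * FiO2 * 100 / SpO2

where MAP is *mean airway pressure* (cmH2O) and FiO2 is a fraction.

Everything downstream — the simulator, ingest, labeling, the boosting
learner and the runtime scorer — keys off the canonical names defined here.
Catalogue order is load-bearing: it is the deterministic tie-break order
used when two candidate weak learners score identically during training.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

__all__ = [
    "FeatureDef",
    "CATALOGUE",
    "FEATURE_NAMES",
    "COMPOSITES",
    "MODEL_FEATURES",
    "DEFAULT_PLAUSIBILITY",
    "DEFAULT_ALIASES",
    "STALENESS_HOURS",
    "staleness_hours",
    "AGE_BIN_EDGES",
    "AGE_MIN",
    "AGE_MAX",
    "AGE_GROUP_LABELS",
    "age_bin_index",
    "canonical_name",
    "catalogue_hash",
    "VASOACTIVE_DRUGS",
    "FLUID_RATE_THRESHOLD",
    "BP_COMPONENT_PAIRS",
]


@dataclass(frozen=True)
class FeatureDef:
    """One chartable clinical variable.

    ``staleness`` classifies the runtime freshness horizon: blood-pressure
    and ventilator measurements go stale after 1 hour, laboratory values and
    other vitals after 24 hours.
    """

    name: str
    unit: str
    panel: str
    staleness: str        # 'bp' | 'vent' | 'lab' | 'vital'
    plaus_lo: float
    plaus_hi: float


# fmt: off
CATALOGUE: tuple[FeatureDef, ...] = (
    # arterial blood gas
    FeatureDef("arterial_ph",          "pH",        "blood_gas", "lab",   6.5,   8.0),
    FeatureDef("bicarbonate",          "mEq/L",     "blood_gas", "lab",   2.0,  60.0),
    FeatureDef("paco2",                "mmHg",      "blood_gas", "lab",   5.0, 250.0),
    FeatureDef("sao2",                 "%",         "blood_gas", "lab",   5.0, 100.0),
    FeatureDef("base_excess",          "mEq/L",     "blood_gas", "lab", -35.0,  30.0),
    FeatureDef("pao2",                 "mmHg",      "blood_gas", "lab",  10.0, 700.0),
    # invasive vitals
    FeatureDef("imbp",                 "mmHg",      "invasive_vitals", "bp", 10.0, 250.0),
    FeatureDef("isbp",                 "mmHg",      "invasive_vitals", "bp", 30.0, 300.0),
    FeatureDef("idbp",                 "mmHg",      "invasive_vitals", "bp",  5.0, 200.0),
    # ventilator parameters
    FeatureDef("pf_ratio",             "ratio",     "ventilator", "vent", 20.0, 700.0),
    FeatureDef("fio2",                 "fraction",  "ventilator", "vent",  0.21,  1.0),
    FeatureDef("mean_airway_pressure", "cmH2O",     "ventilator", "vent",  1.0,  60.0),
    # noninvasive vitals
    FeatureDef("nmbp",                 "mmHg",      "vitals", "bp",    10.0, 250.0),
    FeatureDef("nsbp",                 "mmHg",      "vitals", "bp",    30.0, 300.0),
    FeatureDef("ndbp",                 "mmHg",      "vitals", "bp",     5.0, 200.0),
    FeatureDef("heart_rate",           "bpm",       "vitals", "vital", 20.0, 350.0),
    FeatureDef("respiratory_rate",     "bpm",       "vitals", "vital",  2.0, 150.0),
    FeatureDef("spo2",                 "%",         "vitals", "vital",  5.0, 100.0),
    FeatureDef("temperature",          "Celsius",   "vitals", "vital", 25.0,  45.0),
    # basic metabolic panel
    FeatureDef("glucose",              "mg/dl",     "bmp", "lab",  10.0, 2000.0),
    FeatureDef("chloride",             "mEq/L",     "bmp", "lab",  60.0, 160.0),
    FeatureDef("bun",                  "mg/dl",     "bmp", "lab",   1.0, 300.0),
    FeatureDef("creatinine",           "mg/dl",     "bmp", "lab",   0.05, 25.0),
    FeatureDef("potassium",            "mEq/L",     "bmp", "lab",   1.0,  12.0),
    FeatureDef("sodium",               "mEq/L",     "bmp", "lab", 100.0, 185.0),
    # comprehensive metabolic panel
    FeatureDef("alt",                  "U/L",       "cmp", "lab",   1.0, 8000.0),
    FeatureDef("albumin",              "g/dl",      "cmp", "lab",   0.5,   7.0),
    FeatureDef("total_protein",        "g/dl",      "cmp", "lab",   1.0,  12.0),
    # complete blood count
    FeatureDef("wbc",                  "K/ul",      "cbc", "lab",   0.1, 250.0),
    FeatureDef("rbc",                  "M/ul",      "cbc", "lab",   0.5,   9.0),
    FeatureDef("hemoglobin",           "g/dl",      "cbc", "lab",   2.0,  25.0),
    FeatureDef("platelets",            "K/ul",      "cbc", "lab",   1.0, 2500.0),
    # additional tests
    FeatureDef("magnesium",            "mg/dl",     "additional", "lab",   0.3, 10.0),
    FeatureDef("inr",                  "ratio",     "additional", "lab",   0.3, 15.0),
    FeatureDef("lactic_acid",          "mg/dl",     "additional", "lab",   1.0, 300.0),
    FeatureDef("urine_output",         "ml/kg/h",   "additional", "vital", 0.0,  50.0),
)
# fmt: on

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in CATALOGUE)
assert len(FEATURE_NAMES) == 36

COMPOSITES: tuple[str, ...] = ("si", "oi", "osi")
#: candidate features visible to the learner, catalogue order then composites
MODEL_FEATURES: tuple[str, ...] = FEATURE_NAMES + COMPOSITES

_BY_NAME = {f.name: f for f in CATALOGUE}

DEFAULT_PLAUSIBILITY: dict[str, tuple[float, float]] = {
    f.name: (f.plaus_lo, f.plaus_hi) for f in CATALOGUE
}

STALENESS_HOURS: dict[str, float] = {"bp": 1.0, "vent": 1.0, "lab": 24.0, "vital": 24.0}


def staleness_hours(feature: str, horizons: dict[str, float] | None = None) -> float:
    """Freshness horizon (hours) after which a charted value is treated missing."""
    h = STALENESS_HOURS if horizons is None else horizons
    return h[_BY_NAME[feature].staleness]


# Synonyms seen in flowsheet exports; extendable via an alias file at ingest.
DEFAULT_ALIASES: dict[str, str] = {
    "hr": "heart_rate",
    "pulse": "heart_rate",
    "ph": "arterial_ph",
    "art_ph": "arterial_ph",
    "abe": "base_excess",
    "be": "base_excess",
    "hco3": "bicarbonate",
    "rr": "respiratory_rate",
    "resp_rate": "respiratory_rate",
    "temp": "temperature",
    "sbp": "nsbp",
    "mbp": "nmbp",
    "dbp": "ndbp",
    "map_airway": "mean_airway_pressure",
    "paw": "mean_airway_pressure",
    "uo": "urine_output",
    "lactate": "lactic_acid",
    "hgb": "hemoglobin",
    "plt": "platelets",
    "k": "potassium",
    "na": "sodium",
    "cl": "chloride",
    "mg": "magnesium",
    "prothrombin_time": "inr",
}


def canonical_name(raw: str, aliases: dict[str, str] | None = None) -> str | None:
    """Normalise a raw feature label to its canonical name, or None if unknown."""
    key = raw.strip().lower().replace(" ", "_").replace("-", "_")
    amap = DEFAULT_ALIASES if aliases is None else aliases
    if key in _BY_NAME:
        return key
    return amap.get(key)


# Age handling: five pediatric strata, 1 month to 20 years.
AGE_MIN = 1.0 / 12.0
AGE_MAX = 20.0
AGE_BIN_EDGES: tuple[float, ...] = (AGE_MIN, 1.0, 3.0, 6.0, 12.0, 20.0)
AGE_GROUP_LABELS: tuple[str, ...] = (
    "1-12 months",
    "1-3 years",
    "3-6 years",
    "6-12 years",
    "12-20 years",
)


def age_bin_index(age, edges: tuple[float, ...] = AGE_BIN_EDGES):
    """Index of the age bin containing ``age`` (bins [e_k, e_{k+1}), last closed).

    Ages outside the covered range clamp to the end bins. Accepts scalars or
    numpy arrays.
    """
    import numpy as np

    inner = np.asarray(edges[1:-1])
    idx = np.searchsorted(inner, age, side="right")
    return idx


def catalogue_hash(
    features: tuple[str, ...] = MODEL_FEATURES,
    plausibility: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Stable digest of the feature catalogue + plausibility bounds.

    Stored in serialized models so a loader can refuse a model trained
    against a different catalogue.
    """
    plaus = DEFAULT_PLAUSIBILITY if plausibility is None else plausibility
    parts = []
    for name in features:
        lo, hi = plaus.get(name, (float("nan"), float("nan")))
        parts.append(f"{name}:{lo!r}:{hi!r}")
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


# Intervention-based instability criteria
VASOACTIVE_DRUGS: frozenset[str] = frozenset(
    {"dopamine", "dobutamine", "epinephrine", "norepinephrine", "neosynephrine", "vasopressin"}
)
FLUID_RATE_THRESHOLD = 10.0  # ml/kg/h; a qualifying bolus must exceed this

#: noninvasive component -> matching invasive component, for BP reconciliation
BP_COMPONENT_PAIRS: dict[str, str] = {"nsbp": "isbp", "nmbp": "imbp", "ndbp": "idbp"}
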
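import numpy as np
import pandas as pd
import pytest

from hiikit import SimConfig, simulate_cohort
from hiikit.boosting import train
from hiikit.ingest import plausibility_filter, reconcile_bp
from hiikit.labeling import label_cohort, split_dataset, to_matrix

# Study seeds are fixed up front: 7 for the small unit-test cohort, 2 for the
# signal-recovery study cohort, 1 for the null (zero-effect) cohort.


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_patients=150, seed=7)
    enc, chart, iv = simulate_cohort(cfg)
    chart, _ = plausibility_filter(chart)
    chart = reconcile_bp(chart)
    return cfg, enc, chart, iv


@pytest.fixture(scope="session")
def small_examples(small_cohort):
    _, enc, chart, iv = small_cohort
    examples, ledger = label_cohort(enc, chart, iv, control_seed=101, lead_times=(1.0, 6.0, 12.0))
    return examples, ledger


@pytest.fixture(scope="session")
def small_model(small_examples):
    examples, _ = small_examples
    tr, te = split_dataset(examples, seed=3)
    base = tr[tr["lead_time"].fillna(0.0) == 0.0].reset_index(drop=True)
    X, y, age = to_matrix(base)
    model = train(X, y, age, n_rounds=40)
    return {"model": model, "train": tr, "test": te}


@pytest.fixture(scope="session")
def signal_study():
    """Full study pipeline on the default (signal-on) cohort, n=2000."""
    cfg = SimConfig(n_patients=2000, seed=2)
    enc, chart, iv = simulate_cohort(cfg)
    chart, _ = plausibility_filter(chart)
    chart = reconcile_bp(chart)
    examples, ledger = label_cohort(enc, chart, iv, control_seed=101, lead_times=(1.0, 12.0))
    tr, te = split_dataset(examples, seed=202)
    base_tr = tr[tr["lead_time"].fillna(0.0) == 0.0].reset_index(drop=True)
    X, y, age = to_matrix(base_tr)
    model = train(X, y, age, n_rounds=100)
    return {
        "config": cfg,
        "encounters": enc,
        "chart": chart,
        "interventions": iv,
        "examples": examples,
        "ledger": ledger,
        "train": tr,
        "test": te,
        "X": X,
        "y": y,
        "age": age,
        "model": model,
    }


@pytest.fixture(scope="session")
def null_study():
    """Zero-effect cohort, n=1000: no feature carries any class signal."""
    cfg = SimConfig(n_patients=1000, effect_sizes={}, seed=1)
    enc, chart, iv = simulate_cohort(cfg)
    chart, _ = plausibility_filter(chart)
    chart = reconcile_bp(chart)
    examples, _ = label_cohort(enc, chart, iv, control_seed=101)
    return {"config": cfg, "examples": examples}


@pytest.fixture
def toy_events():
    """Hand-built single-encounter chart for window/staleness tests."""
    t0 = pd.Timestamp("2024-03-01 00:00")
    rows = [
        ("e1", t0 + pd.Timedelta(hours=1), "heart_rate", 120.0, "n/a"),
        ("e1", t0 + pd.Timedelta(hours=2), "arterial_ph", 7.30, "n/a"),
        ("e1", t0 + pd.Timedelta(hours=20), "heart_rate", 135.0, "n/a"),
        ("e1", t0 + pd.Timedelta(hours=23), "nsbp", 90.0, "noninvasive"),
    ]
    return pd.DataFrame(rows, columns=["encounter_id", "time", "feature", "value", "source"])
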
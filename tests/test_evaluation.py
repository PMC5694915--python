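"""Evaluation protocol: AUROC, break-even threshold, prevalence adjustment,
lead-time curves, stratified reports, baselines and summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiikit.evaluation import (
    adjust_predictive_values,
    auroc,
    baseline_models,
    breakeven_threshold,
    leadtime_curve,
    metrics_at_threshold,
    stratified_report,
    summary_stats,
)
from hiikit.labeling import to_matrix


def _brute_force_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([0.9, 0.8, 0.2], [1, 1, -1], 1.0),
        ([0.5, 0.5, 0.5, 0.5], [1, -1, 1, -1], 0.5),
        ([0.8, 0.6, 0.4, 0.2], [1, -1, 1, -1], 0.75),
        ([0.1, 0.9], [1, -1], 0.0),
    ],
)
def test_auroc_known_values(scores, labels, expected):
    assert auroc(np.array(scores), np.array(labels)) == pytest.approx(expected)


@settings(max_examples=60, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_auroc_agrees_with_pairwise_concordance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 60))
    scores = rng.choice(np.linspace(0, 1, 11), size=n)  # coarse grid forces ties
    labels = np.where(rng.random(n) < 0.5, 1, -1)
    if len(set(labels)) < 2:
        labels[0], labels[1] = 1, -1
    assert auroc(scores, labels) == pytest.approx(_brute_force_auroc(scores, labels))


def test_auroc_agrees_with_sklearn_oracle():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    scores = rng.random(200)
    labels = np.where(rng.random(200) < 0.4, 1, -1)
    assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels == 1, scores))


def test_auroc_requires_both_classes():
    with pytest.raises(ValueError):
        auroc(np.array([0.1, 0.2]), np.array([1, 1]))


def test_breakeven_on_four_point_curve():
    scores = np.array([0.9, 0.7, 0.3, 0.1])
    labels = np.array([1, 1, -1, -1])
    thr, sens, prec = breakeven_threshold(scores, labels)
    assert thr == pytest.approx(0.7)
    assert sens == 1.0 and prec == 1.0


def test_breakeven_ties_resolve_to_lower_threshold():
    scores = np.array([0.2, 0.4, 0.6, 0.8])
    labels = np.array([1, -1, 1, -1])  # every cut equally imperfect
    thr, sens, prec = breakeven_threshold(scores, labels)
    gaps = []
    for c in np.unique(scores):
        pred = scores >= c
        s = (pred & (labels == 1)).sum() / 2
        p = (pred & (labels == 1)).sum() / max(pred.sum(), 1)
        gaps.append(abs(s - p))
    assert abs(sens - prec) == pytest.approx(min(gaps))
    candidates = np.unique(scores)[np.isclose(gaps, min(gaps))]
    assert thr == candidates.min()


def test_breakeven_antiranked_flags_degenerate_corner(caplog):
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([1, 1, -1, -1])
    with caplog.at_level("WARNING", logger="hiikit.evaluation"):
        thr, sens, prec = breakeven_threshold(scores, labels)
    assert "degenerate" in caplog.text


@settings(max_examples=40, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_breakeven_is_exhaustively_optimal(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    scores = rng.random(n).round(2)
    labels = np.where(rng.random(n) < 0.5, 1, -1)
    if len(set(labels)) < 2:
        labels[0], labels[1] = 1, -1
    thr, sens, prec = breakeven_threshold(scores, labels)
    best = abs(sens - prec)
    n_pos = (labels == 1).sum()
    for c in np.unique(scores):
        pred = scores >= c
        if pred.sum() == 0:
            continue
        s = (pred & (labels == 1)).sum() / n_pos
        p = (pred & (labels == 1)).sum() / pred.sum()
        assert best <= abs(s - p) + 1e-12


# Printed operating points: (sens, spec, prevalence) -> (PPV, NPV), 2 dp.
PRINTED_TRIPLES = [
    (0.66, 0.78, 0.42, 0.68, 0.76),  # training, 1 h before intervention
    (0.50, 0.77, 0.42, 0.62, 0.68),  # training, 12 h
    (0.76, 0.70, 0.24, 0.45, 0.90),  # validation, 1 h
    (0.66, 0.71, 0.24, 0.42, 0.87),  # validation, 12 h
]


@pytest.mark.parametrize("sens, spec, prev, ppv, npv", PRINTED_TRIPLES)
def test_adjust_predictive_values_reproduces_printed_operating_points(sens, spec, prev, ppv, npv):
    got_ppv, got_npv = adjust_predictive_values(sens, spec, prev)
    assert got_ppv == pytest.approx(ppv, abs=0.01)
    assert got_npv == pytest.approx(npv, abs=0.01)


def test_adjust_predictive_values_edge_cases():
    assert adjust_predictive_values(1.0, 1.0, 0.3) == (1.0, 1.0)
    ppv, npv = adjust_predictive_values(0.0, 1.0, 0.5)
    assert np.isnan(ppv) and npv == pytest.approx(0.5)
    with pytest.raises(ValueError):
        adjust_predictive_values(1.2, 0.5, 0.5)


def test_adjustment_at_sample_prevalence_matches_confusion_matrix():
    rng = np.random.default_rng(1)
    scores = rng.random(300)
    labels = np.where(rng.random(300) < 0.35, 1, -1)
    rep = metrics_at_threshold(scores, labels, 0.5)  # default: sample prevalence
    pred = scores >= 0.5
    tp = ((labels == 1) & pred).sum()
    fp = ((labels == -1) & pred).sum()
    tn = ((labels == -1) & ~pred).sum()
    fn = ((labels == 1) & ~pred).sum()
    assert rep.ppv == pytest.approx(tp / (tp + fp))
    assert rep.npv == pytest.approx(tn / (tn + fn))
    assert rep.positive_lr == pytest.approx(rep.sensitivity / (1 - rep.specificity))


def test_report_invariant_to_example_order():
    rng = np.random.default_rng(5)
    scores = rng.random(100)
    labels = np.where(rng.random(100) < 0.4, 1, -1)
    a = metrics_at_threshold(scores, labels, 0.5)
    perm = rng.permutation(100)
    b = metrics_at_threshold(scores[perm], labels[perm], 0.5)
    assert a.to_row() == b.to_row()


@pytest.mark.parametrize(
    "values, expected",
    [
        ((0.82, 0.77, 0.82, 0.74, 0.75), (0.78, 0.04, 0.74, 0.82)),  # 2 dp
        ((0.5, 0.5, 0.5), (0.5, 0.0, 0.5, 0.5)),
        ((0.0, 1.0), (0.5, 0.7071, 0.0, 1.0)),
    ],
)
def test_summary_stats(values, expected):
    mean, sd, lo, hi = summary_stats(values)
    assert (round(mean, 2), round(sd, 2) if len(values) == 5 else round(sd, 4),
            lo, hi) == pytest.approx(expected)


def test_summary_stats_single_value_sd_undefined():
    mean, sd, lo, hi = summary_stats([0.7])
    assert mean == 0.7 and np.isnan(sd)


def test_leadtime_curve_signal_decays_with_lead(signal_study):
    model = signal_study["model"]
    curve = leadtime_curve(model, signal_study["test"], lead_times=(1.0, 12.0))
    assert list(curve["lead_time_h"]) == [1.0, 12.0]
    a1 = curve.loc[curve["lead_time_h"] == 1.0, "auroc"].iloc[0]
    a12 = curve.loc[curve["lead_time_h"] == 12.0, "auroc"].iloc[0]
    # deterioration ramps toward onset, so the earlier forecast is harder
    assert a1 > a12 > 0.5


def test_leadtime_curve_skips_empty_stratum(signal_study):
    with pytest.warns(UserWarning):
        curve = leadtime_curve(signal_study["model"], signal_study["test"], lead_times=(5.0,))
    assert curve.empty


def test_stratified_age_groups_and_summary(signal_study):
    rep = stratified_report(signal_study["model"], signal_study["test"], "age_group")
    assert len(rep) == 5
    mean, sd, lo, hi = summary_stats(rep["auroc"])
    assert 0.5 < lo <= mean <= 1.0


def test_stratified_feature_masking_orders_full_above_subsets(signal_study):
    rep = stratified_report(signal_study["model"], signal_study["test"], "feature_subset")
    rows = rep.set_index("stratum")["auroc"]
    assert rows["all_features"] >= rows["vitals"] - 0.02
    assert rows["all_features"] >= rows["labs"] - 0.02
    assert rows["vitals"] > 0.5  # each family alone carries signal


def test_stratified_first_intervention_and_unknown_key(signal_study):
    rep = stratified_report(
        signal_study["model"], signal_study["test"], "first_intervention",
        interventions=signal_study["interventions"],
    )
    assert {"first_vasoactive", "first_fluid_bolus"} <= set(rep["stratum"])
    with pytest.raises(ValueError, match="unknown stratum"):
        stratified_report(signal_study["model"], signal_study["test"], "bogus")


def test_stratified_skips_empty_stratum_with_warning(signal_study):
    iv = signal_study["interventions"]
    fluid_only = iv[iv["kind"] == "fluid_bolus"]
    with pytest.warns(UserWarning):
        rep = stratified_report(
            signal_study["model"], signal_study["test"], "first_intervention",
            interventions=fluid_only,
        )
    assert "first_vasoactive" not in set(rep["stratum"])


def test_baselines_carry_signal_but_less_than_full_model(signal_study):
    X, y, age = signal_study["X"], signal_study["y"], signal_study["age"]
    Xt, yt, aget = to_matrix(
        signal_study["test"][signal_study["test"]["lead_time"].fillna(0) == 0].reset_index(drop=True)
    )
    bl = baseline_models(X, y, age)
    full = auroc(signal_study["model"].predict_proba(Xt, aget), yt)
    si = auroc(bl["si_only"].predict_proba(Xt, aget), yt)
    assert {s.feature for s in bl["si_only"].stumps} == {"si"}
    assert {s.feature for s in bl["sbp_only"].stumps} <= {"isbp", "nsbp"}
    assert si > 0.5
    assert full >= si
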
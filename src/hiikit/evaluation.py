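"""Evaluation protocol: ROC by lead time, break-even operating point,
prevalence-adjusted predictive values, stratified analyses and baselines.

AUROC is the Mann-Whitney probability that a random unstable example
outscores a random stable one, with ties counted one half — identical to
trapezoidal integration of the ROC curve. The operating threshold is chosen
at the break-even point where sensitivity (recall) equals precision, and
PPV/NPV are re-derived at a stated prevalence pi by Bayes' rule:

    PPV = sens*pi / (sens*pi + (1-spec)*(1-pi))
    NPV = spec*(1-pi) / (spec*(1-pi) + (1-sens)*pi)

Stratified reports cover the five pediatric age groups, the ventilated
subset, encounters whose first intervention was vasoactive, and feature
subsets — the latter by masking all other features to missing at predict
time, exploiting the ensemble's abstention (retraining per subset is an
option, not the default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import boosting
from .features import AGE_BIN_EDGES, AGE_GROUP_LABELS, FEATURE_NAMES, age_bin_index
from .labeling import derive_composites, to_matrix

__all__ = [
    "MetricsReport",
    "auroc",
    "breakeven_threshold",
    "adjust_predictive_values",
    "metrics_at_threshold",
    "leadtime_curve",
    "stratified_report",
    "baseline_models",
    "summary_stats",
    "FEATURE_SUBSETS",
]

log = logging.getLogger("hiikit.evaluation")

# Feature subsets for the masking ablation. Composite indices are re-derived
# from whatever base features survive the mask.
FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "vitals": (
        "heart_rate", "respiratory_rate", "spo2", "temperature",
        "nsbp", "nmbp", "ndbp", "isbp", "imbp", "idbp", "urine_output",
    ),
    "labs": (
        "arterial_ph", "bicarbonate", "paco2", "sao2", "base_excess", "pao2",
        "glucose", "chloride", "bun", "creatinine", "potassium", "sodium",
        "alt", "albumin", "total_protein", "wbc", "rbc", "hemoglobin",
        "platelets", "magnesium", "inr", "lactic_acid",
    ),
    "ventilator": ("pf_ratio", "fio2", "mean_airway_pressure"),
}


@dataclass
class MetricsReport:
    """Classification metrics for one stratum at one operating point."""

    stratum: str
    auroc: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    positive_lr: float
    prevalence_used: float
    n_pos: int
    n_neg: int
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "stratum", "auroc", "threshold", "sensitivity", "specificity",
            "ppv", "npv", "positive_lr", "prevalence_used", "n_pos", "n_neg",
        )}
        d.update(self.extra)
        return d


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos, neg


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    if np.isnan(scores).any():
        keep = ~np.isnan(scores)
        dropped = int((~keep).sum())
        log.warning("auroc: dropping %d unscored examples", dropped)
        scores, labels = scores[keep], np.asarray(labels)[keep]
        pos, neg = _check_classes(labels)
    r = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def breakeven_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Operating threshold where sensitivity and precision meet.

    Candidates are the observed unique scores (classification rule:
    score >= threshold is positive); the threshold minimising
    |sensitivity - precision| is returned, ties resolved toward the lower
    threshold. Returns (threshold, sensitivity, precision).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _check_classes(labels)
    if np.isnan(scores).any():
        raise ValueError("scores must be finite")
    cand = np.unique(scores)
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    cum_pos = np.concatenate(([0.0], np.cumsum(y_sorted == 1)))
    cum_neg = np.concatenate(([0.0], np.cumsum(y_sorted == -1)))
    n_pos, n_neg = cum_pos[-1], cum_neg[-1]
    k = np.searchsorted(s_sorted, cand, side="left")  # strictly-below count
    tp = n_pos - cum_pos[k]
    fp = n_neg - cum_neg[k]
    predicted = tp + fp
    if not (predicted > 0).any():
        raise ValueError("precision undefined at every candidate threshold")
    sens = tp / n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(predicted > 0, tp / np.maximum(predicted, 1), np.nan)
    gap = np.abs(sens - prec)
    gap = np.where(np.isnan(gap), np.inf, gap)
    j = int(np.argmin(gap))  # np.argmin takes the first (= lowest) threshold
    if not np.isfinite(gap[j]):
        raise ValueError("precision undefined at every candidate threshold")
    if sens[j] in (0.0,) or prec[j] in (0.0,):
        log.warning("break-even landed on a degenerate corner of the PR curve")
    return float(cand[j]), float(sens[j]), float(prec[j])


def adjust_predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV at a stated prevalence, by Bayes' rule.

    A zero denominator yields NaN (undefined marker) rather than an error.
    """
    for v in (sensitivity, specificity, prevalence):
        if not 0.0 <= v <= 1.0:
            raise ValueError("arguments must be in [0, 1]")
    pi = prevalence
    ppv_den = sensitivity * pi + (1.0 - specificity) * (1.0 - pi)
    npv_den = specificity * (1.0 - pi) + (1.0 - sensitivity) * pi
    ppv = sensitivity * pi / ppv_den if ppv_den > 0 else float("nan")
    npv = specificity * (1.0 - pi) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


def metrics_at_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    prevalence: float | None = None,
    stratum: str = "all",
) -> MetricsReport:
    """Full metrics report at a fixed operating threshold (score >= t positive).

    ``prevalence`` defaults to the sample prevalence, in which case PPV/NPV
    equal the raw confusion-matrix values.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    pos, neg = _check_classes(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    pred = scores >= threshold
    tp = int((pred & pos).sum())
    tn = int((~pred & neg).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    if prevalence is None:
        prevalence = n_pos / (n_pos + n_neg)
    ppv, npv = adjust_predictive_values(sens, spec, prevalence)
    plr = sens / (1.0 - spec) if spec < 1.0 else float("inf")
    return MetricsReport(
        stratum=stratum,
        auroc=auroc(scores, labels),
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        positive_lr=plr,
        prevalence_used=prevalence,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _score_examples(model: boosting.BoostModel, examples: pd.DataFrame) -> np.ndarray:
    X, _, age = to_matrix(examples)
    return model.predict_proba(X, age)


def leadtime_curve(
    model: boosting.BoostModel,
    examples: pd.DataFrame,
    lead_times: tuple[float, ...] = tuple(range(1, 13)),
    prevalence: float | None = None,
) -> pd.DataFrame:
    """AUROC (plus operating metrics) as a function of prediction lead time.

    Unstable vectors extracted ``L`` hours before onset are scored against
    the stable examples, whose fixed random reference-time vectors are
    reused at every ``L``.
    """
    stable = examples[examples["label"] == "stable"]
    rows = []
    for L in lead_times:
        unstable = examples[(examples["label"] == "unstable") & (examples["lead_time"] == float(L))]
        if unstable.empty or stable.empty:
            warnings.warn(f"lead time {L} h: empty stratum, skipped")
            continue
        subset = pd.concat([unstable, stable], ignore_index=True)
        scores = _score_examples(model, subset)
        y = np.where(subset["label"] == "unstable", 1, -1)
        keep = ~np.isnan(scores)
        thr, sens, prec = breakeven_threshold(scores[keep], y[keep])
        rep = metrics_at_threshold(scores, y, thr, prevalence, stratum=f"lead_{L}h")
        row = rep.to_row()
        row["lead_time_h"] = float(L)
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_report(
    model: boosting.BoostModel,
    examples: pd.DataFrame,
    strata: str,
    encounters: pd.DataFrame | None = None,
    interventions: pd.DataFrame | None = None,
    threshold: float | None = None,
    prevalence: float | None = None,
    retrain: bool = False,
    train_examples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-stratum metrics over base (lead-time-0 / stable) examples.

    ``strata`` is one of ``age_group``, ``ventilated``, ``first_intervention``
    or ``feature_subset``. Feature subsets are evaluated by masking all other
    features to missing at predict time (abstention absorbs the rest); with
    ``retrain=True`` a fresh model is fitted per subset on
    ``train_examples`` instead. Empty strata are skipped with a warning.
    """
    base = examples[examples["lead_time"].fillna(0.0) == 0.0].reset_index(drop=True)
    rows = []

    def _report(sub: pd.DataFrame, name: str, m: boosting.BoostModel) -> None:
        if sub.empty or sub["label"].nunique() < 2:
            warnings.warn(f"stratum {name!r} empty or single-class, skipped")
            return
        scores = _score_examples(m, sub)
        y = np.where(sub["label"] == "unstable", 1, -1)
        keep = ~np.isnan(scores)
        if threshold is None:
            thr = breakeven_threshold(scores[keep], y[keep])[0]
        else:
            thr = threshold
        rows.append(metrics_at_threshold(scores, y, thr, prevalence, stratum=name).to_row())

    if strata == "age_group":
        bins = age_bin_index(base["age"].to_numpy(), AGE_BIN_EDGES)
        for b, lab in enumerate(AGE_GROUP_LABELS):
            _report(base[bins == b], lab, model)
    elif strata == "ventilated":
        if encounters is None:
            raise ValueError("ventilated strata need the encounters table")
        vent = base["encounter_id"].map(
            encounters.set_index("encounter_id")["ventilated"]
        ).astype(bool)
        _report(base[vent], "ventilated", model)
        _report(base[~vent], "not_ventilated", model)
    elif strata == "first_intervention":
        if interventions is None:
            raise ValueError("first_intervention strata need the interventions table")
        first_kind = (
            interventions.sort_values("time", kind="mergesort")
            .groupby("encounter_id")["kind"]
            .first()
        )
        kind = base["encounter_id"].map(first_kind)
        stable = base["label"] == "stable"
        for k in ("vasoactive", "fluid_bolus"):
            _report(
                pd.concat([base[kind == k], base[stable]], ignore_index=True),
                f"first_{k}",
                model,
            )
    elif strata == "feature_subset":
        for name, feats in FEATURE_SUBSETS.items():
            if retrain:
                if train_examples is None:
                    raise ValueError("retrain mode needs train_examples")
                masked_train = _mask_to_subset(train_examples, feats)
                X, y, age = to_matrix(masked_train)
                m = boosting.train(X, y, age)
                _report(_mask_to_subset(base, feats), name, m)
            else:
                _report(_mask_to_subset(base, feats), name, model)
        _report(base, "all_features", model)
    else:
        raise ValueError(f"unknown stratum key: {strata!r}")
    return pd.DataFrame(rows)


def _mask_to_subset(examples: pd.DataFrame, features: tuple[str, ...]) -> pd.DataFrame:
    """Mask every base feature outside ``features`` to missing, re-derive composites."""
    out = examples.copy()
    for f in FEATURE_NAMES:
        if f not in features:
            out[f] = np.nan
    return derive_composites(out)


def baseline_models(
    X: pd.DataFrame, y: np.ndarray, age: np.ndarray, **train_kwargs
) -> dict[str, boosting.BoostModel]:
    """Age-adjusted single-feature reference models.

    The same learner restricted to systolic blood pressure (both sources) or
    to the shock index, for the model-vs-SBP-vs-SI comparison.
    """
    return {
        "sbp_only": boosting.train(X, y, age, features=("isbp", "nsbp"), **train_kwargs),
        "si_only": boosting.train(X, y, age, features=("si",), **train_kwargs),
    }


def summary_stats(values) -> tuple[float, float, float, float]:
    """(mean, sample SD, min, max); SD is NaN for fewer than two values."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
    return float(v.mean()), sd, float(v.min()), float(v.max())
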
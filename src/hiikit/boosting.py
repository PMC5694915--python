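"""Boosting with abstaining, age-conditioned decision stumps.

The learner is a confidence-weighted ensemble of weak classifiers, each a
lookup table over patient age: within every age bin the stump compares one
clinical feature against a bin-specific threshold and votes *unstable* (+1)
or *stable* (-1); if the feature is missing the stump **abstains** (votes 0),
so missing data needs neither discarding nor imputation.

Training follows the standard confidence-rated construction for abstaining
weak learners. With the weight distribution ``D_t`` over training examples,
a candidate stump splits the total weight into ``W_plus`` (voted correctly),
``W_minus`` (voted incorrectly) and ``W_zero`` (abstained), and is scored by

    Z = W_zero + 2 * sqrt(W_plus * W_minus)

— the normalisation factor of the exponential loss. Each round selects the
candidate minimising Z, assigns it the vote weight

    alpha = 1/2 * ln((W_plus + eps) / (W_minus + eps)),   eps = 1/(2N),

and reweights ``D_{t+1}(i) ∝ D_t(i) * exp(-alpha * y_i * h_t(x_i))`` — an
abstained example's weight is multiplied by exactly 1. Because the weight an
age-binned stump votes correctly decomposes over bins, the Z-minimising
threshold/direction pair can be chosen independently per bin; ties resolve
deterministically (catalogue feature order, then lower threshold, then
high-is-unstable first).

The ensemble margin ``F(x) = sum_t alpha_t h_t(x)`` maps to the instability
probability with the additive-logistic view of boosting,
``p = 1 / (1 + exp(-2 F(x)))``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    AGE_BIN_EDGES,
    DEFAULT_PLAUSIBILITY,
    MODEL_FEATURES,
    STALENESS_HOURS,
    age_bin_index,
    catalogue_hash,
)

__all__ = [
    "AgeFeatureStump",
    "BoostModel",
    "stump_candidates",
    "score_stump",
    "train",
    "margin",
    "predict_proba",
    "cross_validate",
    "selected_features",
]

_FORMAT_VERSION = 1
_EARLY_STOP_Z = 1.0 - 1e-6


@dataclass(frozen=True)
class AgeFeatureStump:
    """One abstaining weak classifier: per-age-bin threshold on one feature.

    ``directions[b]`` is +1 when a value above the bin threshold votes
    unstable (high_is_unstable), -1 when a value below does.
    """

    feature: str
    age_edges: tuple[float, ...]
    thresholds: tuple[float, ...]
    directions: tuple[int, ...]  # +1 high_is_unstable, -1 low_is_unstable
    alpha: float = 0.0

    def __post_init__(self):
        if len(self.thresholds) != len(self.age_edges) - 1:
            raise ValueError("one threshold per age bin required")
        if len(self.directions) != len(self.thresholds):
            raise ValueError("one direction per age bin required")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValueError("directions must be +/-1")
        if any(b <= a for a, b in zip(self.age_edges, self.age_edges[1:])):
            raise ValueError("age bin edges must be strictly increasing")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    def votes(self, x: np.ndarray, age: np.ndarray) -> np.ndarray:
        """Vectorised three-valued vote: +1 unstable, -1 stable, 0 abstain."""
        x = np.asarray(x, dtype=float)
        bins = age_bin_index(age, self.age_edges)
        thr = np.take(np.asarray(self.thresholds), bins)
        sign = np.take(np.asarray(self.directions), bins)
        v = sign * np.where(x > thr, 1, -1)
        return np.where(np.isnan(x), 0, v)


def stump_candidates(
    values: np.ndarray,
    ages: np.ndarray,
    age_edges: tuple[float, ...] = AGE_BIN_EDGES,
    max_thresholds: int = 64,
) -> list[np.ndarray]:
    """Candidate thresholds per age bin for one feature.

    Thresholds are midpoints between consecutive distinct observed in-bin
    values, thinned evenly to ``max_thresholds``; both vote directions are
    considered for every threshold during search. Bins without enough data
    for a midpoint inherit the nearest populated bin's candidates (lower bin
    on ties). A feature with no candidates anywhere cannot be selected.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n_bins = len(age_edges) - 1
    obs = ~np.isnan(values)
    bins = age_bin_index(ages, age_edges)
    own: list[np.ndarray] = []
    for b in range(n_bins):
        v = np.unique(values[obs & (bins == b)])
        if v.size < 2:
            own.append(np.empty(0))
            continue
        mids = (v[:-1] + v[1:]) / 2.0
        if mids.size > max_thresholds:
            idx = np.unique(np.round(np.linspace(0, mids.size - 1, max_thresholds)).astype(int))
            mids = mids[idx]
        own.append(mids)
    populated = [b for b in range(n_bins) if own[b].size]
    if not populated:
        return [np.empty(0) for _ in range(n_bins)]
    out = []
    for b in range(n_bins):
        if own[b].size:
            out.append(own[b])
        else:
            nearest = min(populated, key=lambda p: (abs(p - b), p))
            out.append(own[nearest])
    return out


def score_stump(
    stump: AgeFeatureStump,
    x: np.ndarray,
    age: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
) -> tuple[float, float, float, float]:
    """(W_plus, W_minus, W_zero, Z) of a stump under a weight distribution."""
    v = stump.votes(x, age)
    w = np.asarray(weights, dtype=float)
    wp = float(w[(v != 0) & (v == y)].sum())
    wn = float(w[(v != 0) & (v != y)].sum())
    wz = float(w[v == 0].sum())
    return wp, wn, wz, wz + 2.0 * math.sqrt(wp * wn)


def _best_stump_for_feature(
    x: np.ndarray,
    bins: np.ndarray,
    cand: list[np.ndarray],
    y: np.ndarray,
    w: np.ndarray,
    age_edges: tuple[float, ...],
    feature: str,
) -> tuple[float, float, float, AgeFeatureStump] | None:
    """Z-optimal per-bin (threshold, direction) choice for one feature.

    Total correct-minus-incorrect weight is a sum of independent per-bin
    terms, so maximising it bin by bin (orienting every bin so its correct
    weight dominates) yields the global Z minimiser with alpha >= 0.
    """
    n_bins = len(age_edges) - 1
    obs = ~np.isnan(x)
    thr_out, dir_out = [], []
    wp_tot = wn_tot = 0.0
    any_cand = any(c.size for c in cand)
    if not any_cand:
        return None
    for b in range(n_bins):
        cb = cand[b]
        if cb.size == 0:
            return None
        sel = obs & (bins == b)
        if not sel.any():
            thr_out.append(float(cb[0]))
            dir_out.append(1)
            continue
        xv = x[sel]
        order = np.argsort(xv, kind="stable")
        xs = xv[order]
        wpos = (w[sel] * (y[sel] == 1))[order]
        wneg = (w[sel] * (y[sel] == -1))[order]
        cpos = np.concatenate(([0.0], np.cumsum(wpos)))
        cneg = np.concatenate(([0.0], np.cumsum(wneg)))
        P, N = cpos[-1], cneg[-1]
        k = np.searchsorted(xs, cb, side="right")
        # high_is_unstable: votes +1 above thr -> correct weight:
        wplus_high = (P - cpos[k]) + cneg[k]
        obs_w = P + N
        wplus_low = obs_w - wplus_high
        best_w = np.maximum(wplus_high, wplus_low)
        m = best_w.max()
        # 1e-12 slack so float summation order cannot break mathematical ties
        ties = np.flatnonzero(best_w >= m - 1e-12)
        j = int(ties[0])  # candidates ascend, so first tie = lowest threshold
        direction = 1 if wplus_high[j] >= wplus_low[j] - 1e-12 else -1
        thr_out.append(float(cb[j]))
        dir_out.append(direction)
        wp_b = wplus_high[j] if direction == 1 else wplus_low[j]
        wp_tot += float(wp_b)
        wn_tot += float(obs_w - wp_b)
    wz = float(w[~obs].sum())
    z = wz + 2.0 * math.sqrt(max(wp_tot, 0.0) * max(wn_tot, 0.0))
    stump = AgeFeatureStump(feature, tuple(age_edges), tuple(thr_out), tuple(dir_out))
    return wp_tot, wn_tot, wz, stump


@dataclass
class BoostModel:
    """Ordered abstaining-stump ensemble with probability calibration."""

    stumps: list[AgeFeatureStump] = field(default_factory=list)
    feature_names: tuple[str, ...] = MODEL_FEATURES
    age_edges: tuple[float, ...] = AGE_BIN_EDGES
    eps: float = 0.0
    calibration: str = "logistic_2margin"
    operating_threshold: float | None = None
    catalogue_digest: str = ""
    plausibility: dict = field(default_factory=lambda: dict(DEFAULT_PLAUSIBILITY))
    staleness: dict = field(default_factory=lambda: dict(STALENESS_HOURS))
    history: list[dict] = field(default_factory=list)

    # --- scoring -----------------------------------------------------------
    def margins(self, X: pd.DataFrame, age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble margins for a feature frame; also returns vote counts.

        Rows where every stump abstains get a margin of NaN (insufficient
        inputs) unless the model is empty, in which case margins are 0.
        """
        n = len(X)
        age = np.asarray(age, dtype=float)
        if np.isnan(age).any():
            raise ValueError("age is required for every example")
        F = np.zeros(n)
        n_votes = np.zeros(n, dtype=int)
        for s in self.stumps:
            x = X[s.feature].to_numpy(dtype=float) if s.feature in X.columns else np.full(n, np.nan)
            v = s.votes(x, age)
            F += s.alpha * v
            n_votes += v != 0
        if self.stumps:
            F = np.where(n_votes == 0, np.nan, F)
        return F, n_votes

    def margin(self, vector: pd.Series) -> float:
        """Margin of a single feature vector (needs an ``age`` entry)."""
        if "age" not in vector or pd.isna(vector["age"]):
            raise ValueError("age is required")
        X = vector.drop(labels=["age"]).to_frame().T.astype(float)
        F, n_votes = self.margins(X, np.array([float(vector["age"])]))
        if self.stumps and n_votes[0] == 0:
            raise ValueError("insufficient inputs: every weak classifier abstained")
        return float(np.nan_to_num(F[0]))

    def predict_proba(self, X: pd.DataFrame, age: np.ndarray) -> np.ndarray:
        F, _ = self.margins(X, age)
        return 1.0 / (1.0 + np.exp(-2.0 * F))

    def contributions(self, vector: pd.Series) -> dict[str, float]:
        """Per-feature signed contribution to the margin (sums to margin)."""
        age = float(vector["age"])
        out: dict[str, float] = {}
        for s in self.stumps:
            xv = vector.get(s.feature, np.nan)
            x = np.array([float(xv) if pd.notna(xv) else np.nan])
            v = s.votes(x, np.array([age]))[0]
            if v != 0:
                out[s.feature] = out.get(s.feature, 0.0) + s.alpha * float(v)
        return out

    # --- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format_version": _FORMAT_VERSION,
            "catalogue_digest": self.catalogue_digest,
            "feature_names": list(self.feature_names),
            "age_edges": list(self.age_edges),
            "eps": self.eps,
            "calibration": self.calibration,
            "operating_threshold": self.operating_threshold,
            "plausibility": {k: list(v) for k, v in self.plausibility.items()},
            "staleness_hours": dict(self.staleness),
            "stumps": [
                {
                    "feature": s.feature,
                    "thresholds": list(s.thresholds),
                    "directions": list(s.directions),
                    "alpha": s.alpha,
                }
                for s in self.stumps
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str, expected_digest: str | None = None) -> "BoostModel":
        d = json.loads(text)
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version: {d.get('format_version')}")
        if expected_digest is None:
            expected_digest = catalogue_hash()
        if d["catalogue_digest"] != expected_digest:
            raise ValueError(
                "model was trained against a different feature catalogue "
                f"(digest {d['catalogue_digest']} != {expected_digest})"
            )
        age_edges = tuple(d["age_edges"])
        stumps = [
            AgeFeatureStump(
                s["feature"], age_edges, tuple(s["thresholds"]), tuple(s["directions"]), s["alpha"]
            )
            for s in d["stumps"]
        ]
        return cls(
            stumps=stumps,
            feature_names=tuple(d["feature_names"]),
            age_edges=age_edges,
            eps=d["eps"],
            calibration=d["calibration"],
            operating_threshold=d["operating_threshold"],
            catalogue_digest=d["catalogue_digest"],
            plausibility={k: tuple(v) for k, v in d["plausibility"].items()},
            staleness=dict(d["staleness_hours"]),
        )

    @classmethod
    def load(cls, path: str | Path, expected_digest: str | None = None) -> "BoostModel":
        return cls.from_json(Path(path).read_text(), expected_digest)


def train(
    X: pd.DataFrame,
    y: np.ndarray,
    age: np.ndarray,
    n_rounds: int = 100,
    eps: float | None = None,
    age_edges: tuple[float, ...] = AGE_BIN_EDGES,
    max_thresholds: int = 64,
    features: tuple[str, ...] | None = None,
) -> BoostModel:
    """Fit the abstaining-boosting ensemble.

    ``X`` holds one column per candidate feature (NaN = missing), ``y`` is
    +/-1 (+1 = unstable) and ``age`` is in years (never missing). ``features``
    restricts the candidate set (catalogue order is preserved for
    tie-breaking); ``eps`` defaults to 1/(2N).
    """
    y = np.asarray(y)
    age = np.asarray(age, dtype=float)
    n = len(y)
    if n == 0 or set(np.unique(y)) != {-1, 1}:
        raise ValueError("training set must contain both classes")
    if np.isnan(age).any():
        raise ValueError("age must be present for every example")
    if eps is None:
        eps = 1.0 / (2.0 * n)

    if features is None:
        # full catalogue: a column absent from X is simply always-missing,
        # so adding or removing an all-missing feature cannot change the fit
        features = MODEL_FEATURES
    cols = {
        f: X[f].to_numpy(dtype=float) if f in X.columns else np.full(n, np.nan)
        for f in features
    }
    bins = np.asarray(age_bin_index(age, age_edges))
    cands = {
        f: stump_candidates(cols[f], age, age_edges, max_thresholds) for f in features
    }

    w = np.full(n, 1.0 / n)
    F = np.zeros(n)
    model = BoostModel(
        feature_names=tuple(features),
        age_edges=tuple(age_edges),
        eps=eps,
        catalogue_digest=catalogue_hash(),
    )
    for t in range(n_rounds):
        best = None
        for f in features:  # catalogue order = deterministic tie-break
            res = _best_stump_for_feature(cols[f], bins, cands[f], y, w, age_edges, f)
            if res is None:
                continue
            wp, wn, wz, stump = res
            z = wz + 2.0 * math.sqrt(max(wp, 0.0) * max(wn, 0.0))
            if best is None or z < best[0] - 1e-12:
                best = (z, wp, wn, wz, stump)
        if best is None or best[0] >= _EARLY_STOP_Z:
            if t == 0:
                raise ValueError("no informative feature: every candidate stump has Z ~ 1")
            break
        z, wp, wn, wz, stump = best
        alpha = 0.5 * math.log((wp + eps) / (wn + eps))
        if not math.isfinite(alpha):
            raise FloatingPointError("non-finite alpha; use eps > 0 on separable data")
        if alpha <= 0:
            break  # best stump no better than chance under current weights
        stump = AgeFeatureStump(
            stump.feature, stump.age_edges, stump.thresholds, stump.directions, alpha
        )
        v = stump.votes(cols[stump.feature], age)
        w = w * np.exp(-alpha * y * v)
        w = w / w.sum()
        F = F + alpha * v
        model.stumps.append(stump)
        model.history.append(
            {
                "round": t + 1,
                "feature": stump.feature,
                "Z": z,
                "alpha": alpha,
                "W_plus": wp,
                "W_minus": wn,
                "W_zero": wz,
                "train_error": float(np.mean(np.sign(F) != y)),
                "exp_loss": float(np.mean(np.exp(-y * F))),
                "weight_sum": float(w.sum()),
            }
        )
    return model


def margin(model: BoostModel, vector: pd.Series) -> float:
    """Module-level alias for :meth:`BoostModel.margin`."""
    return model.margin(vector)


def predict_proba(model: BoostModel, X: pd.DataFrame, age: np.ndarray) -> np.ndarray:
    """HII probability in (0, 1): logistic of twice the ensemble margin."""
    return model.predict_proba(X, age)


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    age: np.ndarray,
    groups: np.ndarray,
    k: int = 10,
    seed: int = 0,
    **train_kwargs,
) -> tuple[list[BoostModel], np.ndarray, np.ndarray, np.ndarray]:
    """Patient-level, label-stratified k-fold cross-validation.

    Groups (patients) are shuffled within each label stratum and dealt
    round-robin to folds, so per-fold class counts differ by at most one.
    Returns (per-fold models, pooled out-of-fold scores, their labels, fold
    assignment per example).
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    fold_of_group: dict = {}
    for lab in (1, -1):
        g = np.array(sorted(set(groups[y == lab])))
        if len(g) < k:
            raise ValueError(f"fewer than k={k} patients in class {lab}")
        rng.shuffle(g)
        for i, gid in enumerate(g):
            fold_of_group[gid] = i % k
    fold = np.array([fold_of_group[g] for g in groups])
    scores = np.full(len(y), np.nan)
    models = []
    for f in range(k):
        tr, te = fold != f, fold == f
        m = train(X.loc[tr].reset_index(drop=True), y[tr], age[tr], **train_kwargs)
        scores[te] = m.predict_proba(X.loc[te].reset_index(drop=True), age[te])
        models.append(m)
    return models, scores, y, fold


def selected_features(model: BoostModel) -> list[tuple[str, float]]:
    """Distinct features used by the ensemble, ranked by summed vote weight."""
    sums: dict[str, float] = {}
    for s in model.stumps:
        sums[s.feature] = sums.get(s.feature, 0.0) + abs(s.alpha)
    order = {f: i for i, f in enumerate(model.feature_names)}
    return sorted(sums.items(), key=lambda kv: (-kv[1], order.get(kv[0], 1 << 30)))
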
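"""Independent brute-force reference for the boosting weak-learner search.

Enumerates every candidate stump (full cross-product of per-bin thresholds
and directions, canonically oriented so the correctly-voted weight
dominates), scores each with the direct vote-based decomposition, and picks
the Z minimiser with the documented deterministic tie-break: feature order,
then bin-wise (threshold ascending, high-is-unstable first).
"""

import itertools
import math

import numpy as np

from hiikit.boosting import AgeFeatureStump, score_stump, stump_candidates

_TOL = 1e-12


def oracle_train(X, y, age, n_rounds, age_edges, max_thresholds=8, eps=None):
    y = np.asarray(y)
    age = np.asarray(age, dtype=float)
    n = len(y)
    if eps is None:
        eps = 1.0 / (2.0 * n)
    feats = list(X.columns)
    cands = {
        f: stump_candidates(X[f].to_numpy(dtype=float), age, age_edges, max_thresholds)
        for f in feats
    }
    w = np.full(n, 1.0 / n)
    sequence = []
    for _ in range(n_rounds):
        scored = []
        for fi, f in enumerate(feats):
            per_bin = cands[f]
            if any(c.size == 0 for c in per_bin):
                continue
            x = X[f].to_numpy(dtype=float)
            options = [[(thr, d) for thr in c for d in (1, -1)] for c in per_bin]
            for combo in itertools.product(*options):
                thrs = tuple(tc[0] for tc in combo)
                dirs = tuple(tc[1] for tc in combo)
                stump = AgeFeatureStump(f, tuple(age_edges), thrs, dirs)
                wp, wn, wz, z = score_stump(stump, x, age, y, w)
                if wp < wn - _TOL:
                    continue  # orientation with alpha < 0; its mirror is enumerated too
                key = (fi,) + tuple((thr, 0 if d == 1 else 1) for thr, d in combo)
                scored.append((z, key, stump, wp, wn))
        if not scored:
            break
        zmin = min(s[0] for s in scored)
        if zmin >= 1.0 - 1e-6:
            break
        z, key, stump, wp, wn = min(
            (s for s in scored if s[0] <= zmin + _TOL), key=lambda s: s[1]
        )
        alpha = 0.5 * math.log((wp + eps) / (wn + eps))
        if alpha <= 0:
            break
        sequence.append((stump.feature, stump.thresholds, stump.directions, alpha))
        v = stump.votes(X[stump.feature].to_numpy(dtype=float), age)
        w = w * np.exp(-alpha * y * v)
        w = w / w.sum()
    return sequence
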
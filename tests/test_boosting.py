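"""The abstaining boosting core: candidates, Z scoring, training dynamics,
margins, calibration, cross-validation and serialization."""

import math

import numpy as np
import pandas as pd
import pytest

from hiikit.boosting import (
    AgeFeatureStump,
    BoostModel,
    cross_validate,
    score_stump,
    selected_features,
    stump_candidates,
    train,
)

ONE_BIN = (1 / 12, 20.0)
TWO_BINS = (1 / 12, 6.0, 20.0)


def _ages(n, lo=0.5, hi=18.0, seed=0):
    return np.random.default_rng(seed).uniform(lo, hi, n)


# --- candidates -----------------------------------------------------------

def test_candidates_are_midpoints():
    vals = np.array([1.0, 2.0, 3.0])
    cand = stump_candidates(vals, np.full(3, 5.0), ONE_BIN)
    assert list(cand[0]) == [1.5, 2.5]


def test_candidates_capped():
    vals = np.linspace(0, 1, 10_000)
    cand = stump_candidates(vals, np.full(10_000, 5.0), ONE_BIN, max_thresholds=64)
    assert len(cand[0]) == 64


def test_candidates_empty_for_unmeasured_feature():
    cand = stump_candidates(np.full(5, np.nan), np.full(5, 5.0), ONE_BIN)
    assert all(c.size == 0 for c in cand)


def test_empty_bin_inherits_nearest_populated_bin():
    vals = np.array([1.0, 2.0, 3.0])
    ages = np.array([1.0, 2.0, 3.0])  # all in the young bin
    cand = stump_candidates(vals, ages, TWO_BINS)
    assert list(cand[1]) == list(cand[0]) == [1.5, 2.5]


# --- W/Z decomposition ----------------------------------------------------

def _stump(thr, direction=1, edges=ONE_BIN):
    nb = len(edges) - 1
    return AgeFeatureStump("heart_rate", edges, (thr,) * nb, (direction,) * nb)


def test_score_stump_perfect_separation():
    x = np.array([1.0, 2.0, 10.0, 11.0])
    y = np.array([-1, -1, 1, 1])
    w = np.full(4, 0.25)
    wp, wn, wz, z = score_stump(_stump(5.0), x, _ages(4), y, w)
    assert (wp, wn, wz, z) == (1.0, 0.0, 0.0, 0.0)


def test_score_stump_all_abstain():
    x = np.full(4, np.nan)
    wp, wn, wz, z = score_stump(_stump(5.0), x, _ages(4), np.array([1, 1, -1, -1]), np.full(4, 0.25))
    assert (wp, wn, wz, z) == (0.0, 0.0, 1.0, 1.0)


def test_score_stump_hand_computed_mixture():
    # right on 2, wrong on 1, abstains on 1, uniform weights
    x = np.array([10.0, 11.0, 1.0, np.nan])
    y = np.array([1, 1, 1, -1])
    wp, wn, wz, z = score_stump(_stump(5.0), x, _ages(4), y, np.full(4, 0.25))
    assert (wp, wn, wz) == (0.5, 0.25, 0.25)
    assert z == pytest.approx(0.25 + 2 * math.sqrt(0.5 * 0.25))


def test_weight_partition_sums_to_one():
    rng = np.random.default_rng(3)
    x = np.where(rng.random(50) < 0.3, np.nan, rng.normal(size=50))
    y = np.where(rng.random(50) < 0.5, 1, -1)
    w = rng.random(50)
    w /= w.sum()
    wp, wn, wz, _ = score_stump(_stump(0.0), x, _ages(50), y, w)
    assert wp + wn + wz == pytest.approx(1.0, abs=1e-12)


# --- training -------------------------------------------------------------

def _toy_frame(cols):
    return pd.DataFrame(cols)


def test_separable_1d_reaches_zero_training_error():
    n = 20
    x = np.concatenate([np.linspace(0, 1, 10), np.linspace(2, 3, 10)])
    y = np.array([-1] * 10 + [1] * 10)
    X = _toy_frame({"heart_rate": x})
    model = train(X, y, _ages(n), n_rounds=5, age_edges=ONE_BIN, features=("heart_rate",))
    assert model.history[-1]["train_error"] == 0.0
    assert len(model.stumps) <= 5


def test_informative_but_half_missing_feature_wins_and_abstainers_keep_weight():
    rng = np.random.default_rng(8)
    n = 40
    y = np.array([1, -1] * (n // 2))
    a = np.where(y == 1, 2.0, -2.0) + rng.normal(0, 0.1, n)
    missing = rng.random(n) < 0.5
    a[missing] = np.nan
    X = _toy_frame({"heart_rate": a, "glucose": rng.normal(size=n)})
    age = _ages(n)
    model = train(X, y, age, n_rounds=1, age_edges=ONE_BIN, features=("heart_rate", "glucose"))
    s = model.stumps[0]
    assert s.feature == "heart_rate"
    # replay the weight update: abstained examples' weights change only by the
    # common normaliser, so they stay mutually equal and beat voted-correct ones
    v = s.votes(a, age)
    w1 = np.full(n, 1.0 / n) * np.exp(-s.alpha * y * v)
    w1 /= w1.sum()
    abstained = w1[v == 0]
    assert np.allclose(abstained, abstained[0])
    assert (abstained > w1[(v != 0) & (v == y)].max()).all()


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("edges", [ONE_BIN, TWO_BINS])
def test_train_matches_brute_force_oracle_on_small_instances(seed, edges):
    """Exhaustive Z-minimisation over all candidate stumps reproduces the
    greedy per-bin search, stump for stump and weight for weight."""
    from _oracle import oracle_train

    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    y = np.array([1, -1] * n)[:n]
    cols = {}
    for f in ("heart_rate", "glucose")[: int(rng.integers(1, 3))]:
        x = rng.normal(0, 1, n) + 0.8 * y
        x[rng.random(n) < 0.25] = np.nan
        cols[f] = x
    X = _toy_frame(cols)
    age = rng.uniform(0.2, 19.0, n)
    if np.isnan(list(cols.values())[0]).all():
        pytest.skip("degenerate draw")
    kw = dict(age_edges=edges, max_thresholds=8)
    try:
        model = train(X, y, age, n_rounds=3, features=tuple(X.columns), **kw)
    except ValueError:
        assert oracle_train(X, y, age, 3, edges) == []
        return
    expected = oracle_train(X, y, age, 3, edges)
    got = [(s.feature, s.thresholds, s.directions, s.alpha) for s in model.stumps]
    assert len(got) == len(expected)
    for g, e in zip(got, expected):
        assert g[0] == e[0]
        assert g[1] == pytest.approx(e[1], abs=1e-12)
        assert g[2] == e[2]
        assert g[3] == pytest.approx(e[3], rel=1e-9)


def test_exponential_loss_bounded_by_product_of_z():
    """Classic boosting bound: empirical exp-loss <= prod_t Z_t (eps = 0)."""
    rng = np.random.default_rng(4)
    n = 60
    x = rng.normal(size=n)
    y = np.where(x + rng.normal(0, 1.2, n) > 0, 1, -1)  # noisy, not separable
    X = _toy_frame({"heart_rate": x})
    model = train(X, y, _ages(n), n_rounds=10, eps=0.0, age_edges=ONE_BIN,
                  features=("heart_rate",))
    z_prod = np.prod([h["Z"] for h in model.history])
    assert model.history[-1]["exp_loss"] <= z_prod + 1e-9
    # and the weight distribution stays normalised every round
    for h in model.history:
        assert h["weight_sum"] == pytest.approx(1.0, abs=1e-12)


def test_uninformative_data_raises_no_informative_feature():
    X = _toy_frame({"heart_rate": np.full(6, np.nan)})
    with pytest.raises(ValueError, match="no informative feature"):
        train(X, np.array([1, -1] * 3), _ages(6), features=("heart_rate",))


def test_single_class_rejected():
    X = _toy_frame({"heart_rate": np.arange(5.0)})
    with pytest.raises(ValueError):
        train(X, np.ones(5, dtype=int), _ages(5))


def test_always_missing_feature_is_neutral_bit_for_bit():
    rng = np.random.default_rng(9)
    n = 50
    y = np.array([1, -1] * 25)
    X = _toy_frame({"heart_rate": rng.normal(0, 1, n) + y, "glucose": rng.normal(size=n)})
    age = _ages(n)
    m1 = train(X, y, age, n_rounds=10)
    X2 = X.copy()
    X2["lactic_acid"] = np.nan
    m2 = train(X2, y, age, n_rounds=10)
    assert m1.to_json() == m2.to_json()


# --- margins & calibration ------------------------------------------------

def test_margin_empty_model_is_zero():
    m = BoostModel()
    assert m.margin(pd.Series({"age": 4.0, "heart_rate": 100.0})) == 0.0


def test_margin_single_stump_and_locality():
    s = AgeFeatureStump("heart_rate", ONE_BIN, (100.0,), (1,), alpha=0.5)
    m = BoostModel(stumps=[s])
    assert m.margin(pd.Series({"age": 4.0, "heart_rate": 120.0})) == pytest.approx(0.5)
    assert m.margin(pd.Series({"age": 4.0, "heart_rate": 80.0})) == pytest.approx(-0.5)
    # an unrelated feature's value cannot move the margin
    assert m.margin(
        pd.Series({"age": 4.0, "heart_rate": 120.0, "glucose": 500.0})
    ) == pytest.approx(0.5)


def test_margin_requires_age_and_some_vote():
    s = AgeFeatureStump("heart_rate", ONE_BIN, (100.0,), (1,), alpha=0.5)
    m = BoostModel(stumps=[s])
    with pytest.raises(ValueError, match="age"):
        m.margin(pd.Series({"heart_rate": 120.0}))
    with pytest.raises(ValueError, match="insufficient"):
        m.margin(pd.Series({"age": 4.0, "heart_rate": np.nan}))


def test_probability_is_logistic_and_monotone(small_model):
    model = small_model["model"]
    from hiikit.labeling import to_matrix

    X, _, age = to_matrix(small_model["test"])
    F, _ = model.margins(X, age)
    p = model.predict_proba(X, age)
    keep = ~np.isnan(F)
    assert np.allclose(p[keep], 1 / (1 + np.exp(-2 * F[keep])))
    order = np.argsort(F[keep])
    assert (np.diff(p[keep][order]) >= 0).all()
    # margin 0 maps to probability one half
    empty = BoostModel()
    assert empty.predict_proba(X.iloc[:1], age[:1])[0] == pytest.approx(0.5)


# --- cross-validation -----------------------------------------------------

def test_cross_validation_stratification_and_determinism():
    rng = np.random.default_rng(2)
    n = 100
    y = np.array([1] * 42 + [-1] * 58)
    X = _toy_frame({"heart_rate": rng.normal(0, 1, n) + 0.5 * y})
    age = _ages(n)
    groups = np.array([f"p{i}" for i in range(n)])
    _, s1, _, fold1 = cross_validate(X, y, age, groups, k=10, seed=5, n_rounds=3,
                                     features=("heart_rate",))
    _, s2, _, fold2 = cross_validate(X, y, age, groups, k=10, seed=5, n_rounds=3,
                                     features=("heart_rate",))
    assert np.array_equal(fold1, fold2) and np.allclose(s1, s2)
    pos_per_fold = [((fold1 == f) & (y == 1)).sum() for f in range(10)]
    assert set(pos_per_fold) <= {4, 5}
    with pytest.raises(ValueError):
        cross_validate(X.iloc[:8], y[:8], age[:8], groups[:8], k=10)


def test_two_fold_on_four_examples():
    X = _toy_frame({"heart_rate": [1.0, 2.0, 10.0, 11.0]})
    y = np.array([-1, -1, 1, 1])
    groups = np.array(list("abcd"))
    _, _, _, fold = cross_validate(X, y, _ages(4), groups, k=2, seed=0, n_rounds=1,
                                   features=("heart_rate",), age_edges=ONE_BIN)
    for f in (0, 1):
        assert (y[fold == f] == 1).sum() == 1


# --- feature selection ----------------------------------------------------

def test_selected_features_ranking_and_exclusion():
    rng = np.random.default_rng(11)
    n = 80
    y = np.array([1, -1] * 40)
    X = _toy_frame({
        "heart_rate": 2.0 * y + rng.normal(0, 0.3, n),
        "glucose": rng.normal(size=n),  # pure noise in a separable problem
    })
    model = train(X, y, _ages(n), n_rounds=5)
    sel = selected_features(model)
    assert [f for f, _ in sel] == ["heart_rate"]
    # ranking is invariant under stump reordering
    shuffled = BoostModel(stumps=list(reversed(model.stumps)),
                          feature_names=model.feature_names)
    assert selected_features(shuffled) == sel


# --- serialization --------------------------------------------------------

def test_serialization_round_trips_bit_exactly(small_model, tmp_path):
    model = small_model["model"]
    model.operating_threshold = 0.4375
    path = tmp_path / "model.json"
    model.save(path)
    loaded = BoostModel.load(path)
    assert loaded.to_json() == model.to_json()
    from hiikit.labeling import to_matrix

    X, _, age = to_matrix(small_model["test"])
    np.testing.assert_array_equal(model.predict_proba(X, age), loaded.predict_proba(X, age))


def test_loader_rejects_catalogue_mismatch(small_model, tmp_path):
    model = small_model["model"]
    path = tmp_path / "model.json"
    path.write_text(model.to_json().replace(model.catalogue_digest, "0" * 16))
    with pytest.raises(ValueError, match="catalogue"):
        BoostModel.load(path)
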
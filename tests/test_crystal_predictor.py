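"""Regression-tree training, routing, prediction and suggestions."""

import itertools

import numpy as np
import pytest

from xtalprio.crystal_predictor import (
    DiffractionTreeModel,
    RegressionTree,
    SCREENING_ADVICE,
    predict,
    resolution_to_score,
    suggestions,
    train_tree,
)
from xtalprio.synth_fixtures import CohortSpec, gen_cohort


@pytest.mark.parametrize(
    "outcome,score",
    [
        ("no_crystals", 0),
        ("no_diffraction", 1),
        (15.0, 2),
        (10.01, 2),
        (10.00, 3),
        (4.01, 3),
        (4.00, 4),
        (3.5, 4),
        (2.81, 4),
        (2.80, 5),
        (2.01, 5),
        (2.00, 6),
        (1.2, 6),
    ],
)
def test_resolution_binning_with_inclusive_boundaries(outcome, score):
    assert resolution_to_score(outcome) == score


def test_resolution_binning_rejects_nonsense():
    with pytest.raises(ValueError):
        resolution_to_score(-1.0)
    with pytest.raises(ValueError):
        resolution_to_score("maybe")


def _mono_cohort(xs, ys, feature="l_dis"):
    return [({feature: float(x), "mw_mono": 30000.0}, int(y)) for x, y in zip(xs, ys)]


def test_planted_rule_recovered_with_zero_noise(rng):
    cohort, truth = gen_cohort(CohortSpec(n=60, noise_sigma=0.0), seed=11)
    res = DiffractionTreeModel(cohort).fit()
    root = res.tree.root
    assert root.feature == "l_dis"
    xs = sorted(fv["l_dis"] for fv, _ in cohort)
    below = max(x for x in xs if x <= truth["rule_threshold"])
    above = min(x for x in xs if x > truth["rule_threshold"])
    assert below < root.threshold < above
    assert res.train_mse == pytest.approx(0.0, abs=1e-12)


def test_constant_outcome_cohort_gives_single_leaf():
    cohort = _mono_cohort(range(20), [4] * 20)
    tree = train_tree(cohort)
    assert tree.root.is_leaf
    assert tree.root.mean == 4.0


def test_tiny_cohort_respects_min_leaf_stopping():
    cohort = _mono_cohort([1, 100], [0, 6])
    tree = train_tree(cohort, min_leaf=5)
    assert tree.root.is_leaf


def test_leaf_means_exactly_match_routed_training_outcomes(rng):
    cohort, _ = gen_cohort(CohortSpec(n=120, noise_sigma=1.0, missing_rate=0.2),
                           seed=3)
    tree = train_tree(cohort)
    routed = {}
    for fv, score in cohort:
        leaf, _ = tree.route(fv)
        routed.setdefault(id(leaf), []).append(score)
    for leaf in tree.leaves():
        scores = routed[id(leaf)]
        assert leaf.n == len(scores)
        assert leaf.mean == pytest.approx(np.mean(scores), rel=1e-15)
        assert sum(leaf.train_hist) == len(scores)


def _brute_force_best_split(xs, ys, min_leaf):
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    vals = np.unique(xs)
    sse0 = np.sum((ys - ys.mean()) ** 2)
    best = None
    for lo, hi in zip(vals[:-1], vals[1:]):
        thr = (lo + hi) / 2
        l, r = ys[xs <= thr], ys[xs > thr]
        if len(l) < min_leaf or len(r) < min_leaf:
            continue
        gain = sse0 - np.sum((l - l.mean()) ** 2) - np.sum((r - r.mean()) ** 2)
        if best is None or gain > best[0] + 1e-12:
            best = (gain, thr)
    return best


def test_split_threshold_matches_bruteforce_on_all_small_cohorts():
    """Exhaustive check over single-feature cohorts with n <= 12."""
    rng = np.random.default_rng(0)
    checked = 0
    for n in (4, 6, 8, 12):
        for _ in range(40):
            xs = np.round(rng.uniform(0, 10, n), 1)
            ys = rng.integers(0, 7, n)
            cohort = [({"f": float(x)}, int(y)) for x, y in zip(xs, ys)]
            tree = train_tree(cohort, min_leaf=2, max_depth=1, feature_names=["f"])
            brute = _brute_force_best_split(xs, ys, min_leaf=2)
            if brute is None or brute[0] <= 1e-12:
                assert tree.root.is_leaf
            else:
                assert not tree.root.is_leaf
                assert tree.root.threshold == pytest.approx(brute[1])
            checked += 1
    assert checked == 160


def test_planted_threshold_recovery_across_seeds():
    hits = 0
    for seed in range(20):
        cohort, truth = gen_cohort(CohortSpec(n=100, noise_sigma=0.5), seed=seed)
        tree = train_tree(cohort)
        xs = sorted(fv["l_dis"] for fv, _ in cohort)
        below = max(x for x in xs if x <= truth["rule_threshold"])
        above = min((x for x in xs if x > truth["rule_threshold"]), default=np.inf)
        if (not tree.root.is_leaf and tree.root.feature == "l_dis"
                and below <= tree.root.threshold <= above):
            hits += 1
    assert hits >= 18


def test_crosscheck_against_sklearn_single_split():
    """Independent CART implementation agrees on complete-feature cohorts."""
    from sklearn.tree import DecisionTreeRegressor
    rng = np.random.default_rng(42)
    for _ in range(10):
        xs = rng.uniform(0, 100, 30)
        ys = np.where(xs <= 40, 5, 0) + rng.integers(0, 2, 30)
        cohort = [({"f": float(x)}, int(y)) for x, y in zip(xs, ys)]
        tree = train_tree(cohort, min_leaf=5, max_depth=1, feature_names=["f"])
        sk = DecisionTreeRegressor(max_depth=1, min_samples_leaf=5).fit(
            xs.reshape(-1, 1), ys.astype(float)
        )
        # sklearn stores features as float32, so thresholds agree only to ~1e-7 rel
        assert tree.root.threshold == pytest.approx(sk.tree_.threshold[0], rel=1e-6)


def test_prediction_invariant_to_cohort_permutation(rng):
    cohort, _ = gen_cohort(CohortSpec(n=80, noise_sigma=0.5), seed=9)
    tree1 = train_tree(cohort)
    perm = list(cohort)
    rng.shuffle(perm)
    tree2 = train_tree(perm)
    probe = {"l_dis": 10.0, "mw_mono": 30000.0, "r_dsf": 0.3,
             "yield_score": 3.0, "r_sec": 0.1, "p_maj": 0.9}
    assert predict(tree1, probe).mean_score == predict(tree2, probe).mean_score


def test_missing_feature_routes_to_majority_child_deterministically():
    xs = list(range(12))
    ys = [0] * 8 + [6] * 4  # left (<= 7.5) child holds more samples
    cohort = [({"f": float(x)}, y) for x, y in zip(xs, ys)]
    tree = train_tree(cohort, min_leaf=2, max_depth=1, feature_names=["f"])
    assert not tree.root.is_leaf
    preds = [predict(tree, {"f": None}) for _ in range(5)]
    assert len({p.mean_score for p in preds}) == 1
    bigger = tree.root.left if tree.root.missing_left else tree.root.right
    other = tree.root.right if tree.root.missing_left else tree.root.left
    assert bigger.n >= other.n
    assert preds[0].mean_score == bigger.mean
    assert preds[0].path[0]["imputed"] is True


def test_leaf_mean_of_mixed_outcomes():
    cohort = _mono_cohort([1, 2, 3], [0, 0, 6])
    tree = train_tree(cohort, min_leaf=5)
    pred = predict(tree, {"l_dis": 2.0, "mw_mono": 30000.0})
    assert pred.mean_score == pytest.approx(2.0)
    assert pred.path == []
    assert pred.train_hist[0] == 2 and pred.train_hist[6] == 1


def test_predict_requires_monomer_mw():
    cohort, _ = gen_cohort(CohortSpec(n=40, noise_sigma=0.0), seed=2)
    tree = train_tree(cohort)
    with pytest.raises(ValueError, match="MW"):
        predict(tree, {"l_dis": 5.0})


def test_interpretation_bands():
    cohort = _mono_cohort(range(20), [0] * 10 + [6] * 10)
    tree = train_tree(cohort, min_leaf=5)
    low = predict(tree, {"l_dis": 1.0, "mw_mono": 1.0})
    high = predict(tree, {"l_dis": 19.0, "mw_mono": 1.0})
    assert low.interpretation == "not likely to form crystals"
    assert "2.8" in high.interpretation


def test_suggestions_for_unfavorable_disorder_split():
    cohort = _mono_cohort(range(20), [6] * 10 + [0] * 10)
    tree = train_tree(cohort, min_leaf=5)
    pred = predict(tree, {"l_dis": 19.0, "mw_mono": 30000.0})
    advice = suggestions(pred)
    assert any("disorder" in a for a in advice)


def test_top_category_with_no_crystals_gets_screening_pointer():
    cohort = _mono_cohort(range(20), [6] * 10 + [0] * 10)
    tree = train_tree(cohort, min_leaf=5)
    pred = predict(tree, {"l_dis": 1.0, "mw_mono": 30000.0})
    assert pred.is_top_category
    assert suggestions(pred, no_crystals_yet=True) == [SCREENING_ADVICE]
    assert suggestions(pred, no_crystals_yet=False) == []


def test_tree_json_roundtrip_preserves_routing(rng):
    cohort, _ = gen_cohort(CohortSpec(n=80, noise_sigma=0.5, missing_rate=0.1),
                           seed=17)
    tree = train_tree(cohort)
    clone = RegressionTree.from_json(tree.to_json())
    for fv, _ in cohort[:25]:
        a, pa = tree.route(fv)
        b, pb = clone.route(fv)
        assert a.mean == b.mean and pa == pb


def test_from_dataframe_constructor():
    import pandas as pd
    rows = [{"l_dis": float(x), "mw_mono": 30000.0,
             "r_dsf": np.nan, "yield_score": np.nan, "r_sec": np.nan,
             "p_maj": np.nan, "score": 5 if x <= 10 else 0}
            for x in range(24)]
    df = pd.DataFrame(rows)
    res = DiffractionTreeModel.from_dataframe(df).fit()
    assert res.tree.root.feature == "l_dis"
    assert "regression tree" in res.summary()
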
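"""Feature-selection procedures: wrappers, CFS and PCA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from emgburg import (Dataset, SelectionConfig, cfs_merit, cfs_subset_eval,
                     forward_selection, make_cv_evaluator, pca_transform,
                     plus_l_take_away_r)


def _dataset(features: dict, labels):
    n = len(labels)
    return Dataset(features=pd.DataFrame(features),
                   labels=pd.Series(labels, name="class"),
                   subjects=pd.Series(np.zeros(n, dtype=int)),
                   trials=pd.Series(np.arange(n)))


def _two_class(n_per=20, seed=0):
    """One perfectly separating feature, one exact duplicate of it, one
    pure-noise feature."""
    rng = np.random.default_rng(seed)
    labels = ["a"] * n_per + ["b"] * n_per
    sep = np.concatenate([rng.normal(-3, 0.3, n_per), rng.normal(3, 0.3, n_per)])
    return _dataset({"sep": sep, "dup": sep.copy(),
                     "noise": rng.standard_normal(2 * n_per)}, labels)


EVALUATOR = make_cv_evaluator(k_folds=5, seed=0)


def test_ltr_removes_duplicate_without_accuracy_loss():
    ds = _two_class()
    ref = EVALUATOR(ds)
    result = plus_l_take_away_r(ds, EVALUATOR, SelectionConfig(tolerance=0.0))
    # one of the duplicated pair survives, the other is gone
    assert ("sep" in result.selected) != ("dup" in result.selected) or \
        ("sep" in result.selected and "dup" not in result.selected)
    final_score = EVALUATOR(ds.select(result.selected))
    assert final_score >= ref - 1e-12


def test_ltr_removes_noise_feature_first():
    ds = _two_class()
    result = plus_l_take_away_r(ds, EVALUATOR, SelectionConfig(tolerance=0.0))
    removed = result.trace[result.trace.action == "removed"]
    assert len(removed) >= 1
    # the first removal is never the only separating information
    assert set(result.selected) & {"sep", "dup"}


def test_ltr_keeps_everything_when_all_features_needed():
    # XOR-style: both features jointly needed, 1-NN on either alone is poor
    rng = np.random.default_rng(1)
    n = 40
    a = np.repeat([0, 0, 1, 1], n // 4) + rng.normal(0, 0.05, n)
    b = np.repeat([0, 1, 0, 1], n // 4) + rng.normal(0, 0.05, n)
    labels = np.where(np.repeat([0, 1, 1, 0], n // 4) == 1, "odd", "even")
    ds = _dataset({"a": a, "b": b}, list(labels))
    result = plus_l_take_away_r(ds, EVALUATOR, SelectionConfig(tolerance=0.0))
    assert set(result.selected) == {"a", "b"}


def test_ltr_never_below_reference_minus_tolerance(small_k_dataset):
    sub = small_k_dataset.select(small_k_dataset.feature_names[:6])
    ref = EVALUATOR(sub)
    result = plus_l_take_away_r(sub, EVALUATOR, SelectionConfig(tolerance=0.05))
    assert EVALUATOR(sub.select(result.selected)) >= ref - 0.05 - 1e-12


def test_forward_selection_finds_separating_feature():
    ds = _two_class()
    result = forward_selection(ds, EVALUATOR)
    assert result.selected[0] in ("sep", "dup")
    scores = result.trace[result.trace.action == "added"].score.to_numpy()
    assert np.all(np.diff(scores) > 0) if scores.size > 1 else True


def test_forward_selection_trace_strictly_increases(small_k_dataset):
    sub = small_k_dataset.select(small_k_dataset.feature_names[:8])
    result = forward_selection(sub, EVALUATOR)
    scores = result.trace[result.trace.action == "added"].score.to_numpy()
    assert np.all(np.diff(scores) > 0)


def test_forward_selection_on_pure_noise_is_small_and_near_chance():
    rng = np.random.default_rng(2)
    n = 120
    labels = list(np.repeat(list("abcdef"), n // 6))
    ds = _dataset({f"n{i}": rng.standard_normal(n) for i in range(4)}, labels)
    result = forward_selection(ds, EVALUATOR)
    assert len(result.selected) <= 2
    if result.selected:
        score = EVALUATOR(ds.select(result.selected))
        assert score < 1 / 6 + 0.25  # chance-ish for six balanced classes


def test_forward_selection_seeds_are_kept_and_pool_respected(small_k_dataset):
    seeds = ["K1_ch1", "K1_ch2"]
    pool = ["K2_ch1", "K2_ch2", "K3_ch1"]
    result = forward_selection(small_k_dataset, EVALUATOR, seed_features=seeds,
                               candidate_pool=pool)
    assert result.selected[:2] == seeds
    assert set(result.selected[2:]) <= set(pool)
    with pytest.raises(KeyError):
        forward_selection(small_k_dataset, EVALUATOR, seed_features=["bogus"])


# ---------------------------------------------------------------------------
# CFS


def _exhaustive_cfs(ds):
    best, best_merit = (), -np.inf
    names = ds.feature_names
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            m = cfs_merit(ds, subset)
            if m > best_merit + 1e-12:
                best, best_merit = subset, m
    return set(best), best_merit


def test_cfs_equals_exhaustive_optimum_on_small_sets():
    rng = np.random.default_rng(3)
    n = 60
    y = np.repeat([0, 1, 2], n // 3)
    labels = [("a", "b", "c")[v] for v in y]
    informative = y + rng.normal(0, 0.4, n)
    unique = (y == 1).astype(float) + rng.normal(0, 0.4, n)
    ds = _dataset({
        "inf": informative, "inf_dup": informative + rng.normal(0, 0.01, n),
        "uni": unique, "noise1": rng.standard_normal(n),
        "noise2": rng.standard_normal(n),
    }, labels)
    result = cfs_subset_eval(ds)
    exp_set, exp_merit = _exhaustive_cfs(ds)
    assert cfs_merit(ds, result.selected) == pytest.approx(exp_merit, abs=1e-10)
    assert set(result.selected) == exp_set


def test_cfs_duplicate_feature_not_kept_twice():
    ds = _two_class()
    result = cfs_subset_eval(ds)
    assert not {"sep", "dup"} <= set(result.selected)
    assert {"sep", "dup"} & set(result.selected)


def test_cfs_single_feature_merit_is_class_correlation():
    rng = np.random.default_rng(4)
    y = np.repeat([0, 1], 30)
    x = y + rng.normal(0, 0.5, 60)
    ds = _dataset({"x": x}, [("a", "b")[v] for v in y])
    m = cfs_merit(ds, ["x"])
    assert 0 < m <= 1
    assert cfs_subset_eval(ds).selected == ["x"]


def test_cfs_merit_grows_with_k_for_uncorrelated_equal_features():
    # closed form: merit = k r / sqrt(k) = r sqrt(k) when r_ff = 0
    rng = np.random.default_rng(5)
    n = 4000
    y = np.repeat([0.0, 1.0], n // 2)
    prev = 0.0
    ds = _dataset({f"f{i}": y + rng.normal(0, 3.0, n) for i in range(3)},
                  [("a", "b")[int(v)] for v in y])
    for k in (1, 2, 3):
        m = cfs_merit(ds, ds.feature_names[:k])
        assert m > prev
        prev = m


def test_cfs_constant_feature_scores_zero():
    rng = np.random.default_rng(6)
    y = np.repeat([0, 1], 20)
    ds = _dataset({"const": np.ones(40), "x": y + rng.normal(0, 0.3, 40)},
                  [("a", "b")[v] for v in y])
    assert cfs_merit(ds, ["const"]) == 0.0
    assert cfs_subset_eval(ds).selected == ["x"]


# ---------------------------------------------------------------------------
# PCA


def test_pca_axis_aligned_recovers_variances():
    rng = np.random.default_rng(7)
    n = 2000
    data = {"a": 3.0 * rng.standard_normal(n), "b": 1.0 * rng.standard_normal(n),
            "c": 0.2 * rng.standard_normal(n)}
    ds = _dataset(data, ["x"] * n)
    out = pca_transform(ds, variance_retained=1.0, standardize=False)
    variances = out.X.var(axis=0)
    assert np.all(np.diff(variances) <= 1e-9)
    np.testing.assert_allclose(np.sort(variances)[::-1],
                               [9.0, 1.0, 0.04], rtol=0.15)


def test_pca_full_variance_is_invertible(small_k_dataset):
    out = pca_transform(small_k_dataset, variance_retained=1.0,
                        standardize=False)
    # rank preserved: total variance matches the original
    assert out.X.var(axis=0).sum() == pytest.approx(
        small_k_dataset.X.var(axis=0).sum(), rel=1e-8)


def test_pca_components_uncorrelated(small_k_dataset):
    out = pca_transform(small_k_dataset, variance_retained=0.95)
    corr = np.corrcoef(out.X, rowvar=False)
    off = corr - np.diag(np.diag(corr))
    assert np.max(np.abs(off)) < 1e-8
    variances = out.X.var(axis=0)
    assert np.all(np.diff(variances) <= 1e-9)


def test_pca_rejects_degenerate_input():
    ds = _dataset({"a": [1.0]}, ["x"])
    with pytest.raises(ValueError, match="2 instances"):
        pca_transform(ds)
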
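"""Frequency processing, the weighted pseudo-ROC and the GA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metchange.siderfinder import (
    GAConfig,
    adjust_frequencies,
    consensus_from_folds,
    cross_validate,
    filter_side_effects,
    process_frequencies,
    pseudo_roc_auc,
    run_ga,
    score_samples,
)
from metchange.synthetic import FixtureSpec, make_side_effect_dataset


def _freq_table(rows):
    return pd.DataFrame(
        rows, columns=["drug", "side_effect", "study_id", "arm", "freq_min", "freq_max"]
    )


class TestProcessFrequencies:
    def test_treated_minus_placebo(self):
        table = _freq_table(
            [
                ("d1", "se", "s1", "treated", 0.10, 0.30),
                ("d1", "se", "s2", "placebo", 0.05, 0.05),
            ]
        )
        assert process_frequencies(table, "se")["d1"] == pytest.approx(0.15)

    def test_median_of_treated_studies_without_placebo(self):
        table = _freq_table(
            [
                ("d1", "se", "s1", "treated", 0.15, 0.25),  # mean 0.20
                ("d1", "se", "s2", "treated", 0.05, 0.15),  # mean 0.10
            ]
        )
        assert process_frequencies(table, "se")["d1"] == pytest.approx(0.15)

    def test_negative_difference_clamped(self):
        table = _freq_table(
            [
                ("d1", "se", "s1", "treated", 0.02, 0.02),
                ("d1", "se", "s2", "placebo", 0.05, 0.05),
            ]
        )
        assert process_frequencies(table, "se")["d1"] == 0.0

    def test_other_side_effects_ignored(self):
        table = _freq_table(
            [
                ("d1", "se", "s1", "treated", 0.2, 0.2),
                ("d1", "other", "s2", "treated", 0.9, 0.9),
            ]
        )
        assert process_frequencies(table, "se")["d1"] == pytest.approx(0.2)


def test_filter_side_effects_boundary():
    freq = {
        "few": {f"s{i}": 0.1 for i in range(29)},
        "enough": {f"s{i}": 0.1 for i in range(30)},
    }
    assert filter_side_effects(freq, 30) == ["enough"]
    assert set(filter_side_effects(freq, 0)) == {"few", "enough"}


class TestAdjustFrequencies:
    def test_decade_grid(self):
        w = adjust_frequencies(pd.Series({"a": 0.0, "b": 1e-3, "c": 1e-2, "d": 1e-1}))
        assert w.tolist() == [0.0, 1.0, 2.0, 3.0]

    def test_lowest_positive_is_one(self):
        w = adjust_frequencies(pd.Series({"a": 0.007, "b": 0.07}))
        assert w["a"] == pytest.approx(1.0)
        assert w["b"] == pytest.approx(2.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            adjust_frequencies(pd.Series({"a": 0.0}))


class TestScoreSamples:
    def test_inner_product(self):
        scores = pd.DataFrame({"m1": [2.0], "m2": [0.5]}, index=["s"])
        out = score_samples({"m1": 1, "m2": -1}, scores)
        assert out["s"] == pytest.approx(1.5)

    def test_all_zero_signature(self):
        scores = pd.DataFrame({"m1": [2.0], "m2": [0.5]}, index=["s"])
        assert (score_samples({"m1": 0, "m2": 0}, scores) == 0).all()

    def test_missing_entries_contribute_zero(self):
        scores = pd.DataFrame({"m1": [2.0], "m2": [np.nan]}, index=["s"])
        assert score_samples({"m1": 1, "m2": -1}, scores)["s"] == pytest.approx(2.0)


# -- the weighted ROC ---------------------------------------------------------


def brute_force_pseudo_auc(scores, weights):
    """Independent threshold-sweep construction: call samples with score
    >= each descending distinct score, accumulate weighted TPR / counted
    FPR, explicit trapezoids."""
    scores = np.asarray(scores, float)
    weights = np.asarray(weights, float)
    total_w = weights.sum()
    n_neg = (weights == 0).sum()
    pts = [(0.0, 0.0)]
    for thr in sorted(set(scores), reverse=True):
        called = scores >= thr
        fpr = (called & (weights == 0)).sum() / n_neg
        tpr = weights[called].sum() / total_w
        pts.append((fpr, tpr))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def test_perfect_separation_gives_one():
    s = np.array([5.0, 4.0, 3.0, 1.0, 0.5])
    w = np.array([2.0, 1.0, 3.0, 0.0, 0.0])
    assert pseudo_roc_auc(s, w) == 1.0


def test_worked_example_five_sixths():
    assert pseudo_roc_auc(np.array([3.0, 2, 1, 0]), np.array([2.0, 0, 1, 0])) == pytest.approx(5 / 6, abs=1e-12)


def test_all_tied_gives_half():
    assert pseudo_roc_auc(np.ones(6), np.array([1.0, 0, 2, 0, 1, 0])) == pytest.approx(0.5, abs=1e-12)


def test_degenerate_classes_error():
    with pytest.raises(ValueError):
        pseudo_roc_auc(np.arange(3.0), np.zeros(3))
    with pytest.raises(ValueError):
        pseudo_roc_auc(np.arange(3.0), np.ones(3))


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=150, derandomize=True)
def test_matches_brute_force_sweep(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 50))
    scores = np.round(rng.normal(size=n), 1)  # rounded to force ties
    weights = np.where(rng.random(n) < 0.5, 0.0, rng.choice([1.0, 2.0, 3.0], n))
    if weights.sum() == 0 or (weights == 0).sum() == 0:
        return
    assert pseudo_roc_auc(scores, weights) == pytest.approx(
        brute_force_pseudo_auc(scores, weights), abs=1e-12
    )


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_unit_weights_reduce_to_classical_auc(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    scores = np.round(rng.normal(size=n), 1)
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        return
    u = stats.mannwhitneyu(scores[labels], scores[~labels], alternative="two-sided")
    classical = u.statistic / (labels.sum() * (~labels).sum())
    assert pseudo_roc_auc(scores, labels.astype(float)) == pytest.approx(classical, abs=1e-12)


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_monotone_transform_invariance_and_reversal(seed):
    rng = np.random.default_rng(seed)
    n = 20
    scores = rng.normal(size=n)
    weights = np.where(rng.random(n) < 0.5, 0.0, 1.0 + rng.random(n))
    if weights.sum() == 0 or (weights == 0).sum() == 0:
        return
    auc = pseudo_roc_auc(scores, weights)
    assert 0.0 <= auc <= 1.0
    assert pseudo_roc_auc(np.exp(scores) * 3 + 1, weights) == pytest.approx(auc, abs=1e-12)
    assert pseudo_roc_auc(-scores, weights) == pytest.approx(1 - auc, abs=1e-12)


# -- genetic algorithm --------------------------------------------------------


def _planted_single(seed=0, n=60, m=50):
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2 == 0
    X = rng.normal(size=(n, m))
    X[:, 7] = np.where(labels, 10.0, -10.0)  # perfect discriminator
    scores = pd.DataFrame(X, columns=[f"m{i}" for i in range(m)])
    weights = pd.Series(np.where(labels, 1.0, 0.0), index=scores.index)
    return scores, weights


def test_ga_finds_planted_perfect_metabolite():
    scores, weights = _planted_single()
    res = run_ga(scores, weights, GAConfig(max_generations=40, stall_generations=15, seed=3))
    assert res.auc == pytest.approx(1.0)
    assert res.signature["m7"] == 1


def test_ga_deterministic_for_fixed_seed():
    scores, weights = _planted_single(seed=2)
    cfg = GAConfig(max_generations=15, seed=11)
    a = run_ga(scores, weights, cfg)
    b = run_ga(scores, weights, cfg)
    assert a.auc == b.auc
    assert (a.signature == b.signature).all()


def test_ga_zero_generations_degenerate_run():
    scores, weights = _planted_single(seed=4, n=20, m=10)
    res = run_ga(scores, weights, GAConfig(population_size=2, max_generations=0, seed=0))
    assert 0.0 <= res.auc <= 1.0
    assert res.signature.abs().sum() <= 20


def test_ga_beats_best_single_metabolite():
    rng = np.random.default_rng(5)
    n, m = 40, 8
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        labels[0] = True
        labels[1] = False
    X = rng.normal(size=(n, m)) + np.outer(labels, rng.normal(size=m))
    scores = pd.DataFrame(X, columns=[f"m{i}" for i in range(m)])
    weights = pd.Series(labels.astype(float), index=scores.index)
    best_single = max(
        pseudo_roc_auc(sgn * X[:, j], weights.to_numpy())
        for j in range(m)
        for sgn in (1, -1)
    )
    res = run_ga(scores, weights, GAConfig(max_generations=60, stall_generations=20, seed=1))
    assert res.auc >= best_single - 1e-12


def test_ga_respects_cardinality_cap():
    scores, weights = _planted_single(seed=6)
    res = run_ga(
        scores, weights, GAConfig(max_predictors=5, max_generations=20, seed=2)
    )
    assert (res.signature != 0).sum() <= 5


def test_ga_rejects_single_class():
    scores, _ = _planted_single()
    with pytest.raises(ValueError):
        run_ga(scores, pd.Series(1.0, index=scores.index), GAConfig(max_generations=1))


# -- cross-validation ---------------------------------------------------------


class TestConsensus:
    def _folds(self, col):
        return pd.DataFrame({"m": col, "other": [0] * len(col)})

    def test_five_of_ten_included(self):
        folds = self._folds([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        _, cons = consensus_from_folds(folds, threshold=4)
        assert cons["m"] == 1

    def test_three_of_ten_excluded(self):
        folds = self._folds([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        _, cons = consensus_from_folds(folds, threshold=4)
        assert cons["m"] == 0

    def test_cancelling_signs_excluded(self):
        folds = self._folds([1, 1, -1, -1, 0, 0, 0, 0, 0, 0])
        summed, cons = consensus_from_folds(folds, threshold=4)
        assert summed["m"] == 0 and cons["m"] == 0

    def test_count_mode(self):
        folds = self._folds([1, 1, -1, 1, 0, 0, 0, 0, 0, 0])
        _, cons_sum = consensus_from_folds(folds, threshold=4, mode="sum")
        _, cons_cnt = consensus_from_folds(folds, threshold=4, mode="count")
        assert cons_sum["m"] == 0  # |sum| = 2 < 4
        assert cons_cnt["m"] == 1  # appears in 4 folds, net positive


def test_cross_validate_recovers_planted_signature():
    ds = make_side_effect_dataset(FixtureSpec(seed=1, n_samples=120, n_metabolites=20))
    w = adjust_frequencies(ds.frequencies)
    cv = cross_validate(
        ds.scores, w, GAConfig(max_generations=40, stall_generations=15, seed=1), folds=10
    )
    hits = sum(1 for m, v in ds.signature.items() if v != 0 and cv.consensus[m] == v)
    assert hits >= 2
    assert np.median(cv.test_auc) > 0.8
    assert len(cv.fold_signatures) == 10


def test_cross_validate_needs_enough_per_class():
    ds = make_side_effect_dataset(FixtureSpec(seed=0, n_samples=12, n_metabolites=5))
    w = adjust_frequencies(ds.frequencies)
    with pytest.raises(ValueError):
        cross_validate(ds.scores, w, GAConfig(max_generations=1), folds=10)
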
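"""Selector contracts, fallbacks, independent oracles, and the JSC index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from refnoise import (
    DatasetProfile,
    FeatureTable,
    ValidationError,
    generate,
    jaccard_multi,
    run_selector,
    select_lasso,
    select_mannwhitney,
    select_mrmr,
    select_rfe,
)
from refnoise.feature_selection import default_n_target


def _table(X, prefix="f"):
    n, p = X.shape
    return FeatureTable(
        tuple(f"s{i}" for i in range(n)), tuple(f"{prefix}{j}" for j in range(p)), X
    )


class TestMannWhitney:
    def test_perfect_separator_selected_with_tiny_p(self, rng):
        y = np.repeat([0, 1], 20)
        X = np.column_stack([np.where(y == 1, 10.0, 0.0) + 0.01 * rng.normal(size=40),
                             rng.normal(size=40)])
        res = select_mannwhitney(_table(X), y)
        assert "f0" in res.selected
        assert res.scores["f0"] < 1e-6
        assert not res.fallback_used

    def test_identical_distribution_feature_not_selected(self, rng):
        y = np.repeat([0, 1], 25)
        shared = rng.normal(size=25)
        X = np.concatenate([shared, shared])[:, None]  # identical in both classes
        res = select_mannwhitney(_table(X), y)
        assert res.fallback_used  # nothing passes, so the fallback returns all
        assert res.scores["f0"] > 0.9

    def test_constant_feature_gets_p_one(self, rng):
        y = np.repeat([0, 1], 10)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        res = select_mannwhitney(_table(X), y)
        assert res.scores["f0"] == 1.0
        assert "f0" not in res.selected or res.fallback_used

    def test_pure_noise_fallback_contract(self, rng):
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 15))
        res = select_mannwhitney(_table(X), y, alpha=1e-12)
        assert res.fallback_used
        assert len(res.selected) == 15


class TestLasso:
    def test_recovers_strong_feature_across_seeds(self, rng):
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            y = np.repeat([0, 1], 100)
            X = local.normal(size=(200, 21))
            X[:, 0] += 3.0 * y  # d = 3 signal in the first column
            res = select_lasso(_table(X), y, seed=seed)
            hits += "f0" in res.selected
        assert hits >= 19

    def test_infinite_penalty_falls_back_to_all_features(self, rng):
        y = np.repeat([0, 1], 25)
        X = rng.normal(size=(50, 8))
        res = select_lasso(_table(X), y, Cs=[1e-8])  # penalty so strong nothing survives
        assert res.fallback_used
        assert len(res.selected) == 8


class TestRFE:
    def test_signal_feature_survives_to_last(self):
        local = np.random.default_rng(77)
        y = np.repeat([0, 1], 100)
        X = local.normal(size=(200, 3))
        X[:, 1] += 3.0 * y
        res = select_rfe(_table(X), y, n_target=1)
        assert res.selected == ("f1",)

    def test_identity_when_target_is_p(self, rng):
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 4))
        res = select_rfe(_table(X), y, n_target=4)
        assert set(res.selected) == {"f0", "f1", "f2", "f3"}

    def test_deterministic(self, rng):
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 12))
        X[:, 2] += 1.0 * y
        t = _table(X)
        assert select_rfe(t, y, 4).selected == select_rfe(t, y, 4).selected


class TestMRMR:
    def test_duplicate_of_top_feature_not_chosen_second(self):
        local = np.random.default_rng(5)
        y = np.repeat([0, 1], 50)
        best = local.normal(size=100) + 2.0 * y
        X = np.column_stack([best, best.copy(), local.normal(size=100)])
        res = select_mrmr(_table(X), y, n_target=2)
        assert res.selected[0] == "f0"  # tie between identical copies breaks by order
        assert res.selected[1] == "f2"  # the exact copy is fully redundant

    def test_null_first_pick_uniform_over_features(self):
        # with no signal, which feature ranks most relevant is uniform
        counts = np.zeros(5)
        for seed in range(200):
            local = np.random.default_rng(seed)
            y = np.repeat([0, 1], 20)
            X = local.normal(size=(40, 5))
            res = select_mrmr(_table(X), y, n_target=1)
            counts[int(res.selected[0][1:])] += 1
        assert chisquare(counts).pvalue > 0.001

    def test_matches_exhaustive_greedy_oracle_small(self):
        from sklearn.metrics import mutual_info_score

        from refnoise.feature_selection import _equal_frequency_bins

        for seed in range(5):
            local = np.random.default_rng(seed)
            n, p, k = 40, 6, 4
            y = np.repeat([0, 1], n // 2)
            X = local.normal(size=(n, p))
            X[:, 0] += 1.5 * y
            nbins = int(np.ceil(np.sqrt(n)))
            D = np.column_stack([_equal_frequency_bins(X[:, j], nbins) for j in range(p)])
            chosen: list[int] = []
            for _ in range(k):
                best, best_score = None, -np.inf
                for j in range(p):
                    if j in chosen:
                        continue
                    rel = mutual_info_score(D[:, j], y)
                    red = np.mean([mutual_info_score(D[:, j], D[:, s]) for s in chosen]) if chosen else 0.0
                    if rel - red > best_score + 1e-12:
                        best, best_score = j, rel - red
                chosen.append(best)
            res = select_mrmr(_table(X), y, n_target=k)
            assert [int(f[1:]) for f in res.selected] == chosen


class TestJaccardMulti:
    def test_pairwise_example(self):
        assert jaccard_multi([{1, 2, 3}, {2, 3, 4}]) == 0.5

    def test_identical_sets_give_one(self):
        assert jaccard_multi([{1, 2}] * 20) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert jaccard_multi([{1, 2}, {3, 4}]) == 0.0

    def test_requires_two_sets(self):
        with pytest.raises(ValidationError):
            jaccard_multi([{1}])

    def test_empty_union_convention(self):
        assert jaccard_multi([set(), set()]) == 1.0

    @given(
        st.lists(st.sets(st.integers(0, 8), max_size=6), min_size=2, max_size=6)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_invariant_and_monotone(self, sets):
        base = jaccard_multi(sets)
        assert jaccard_multi(list(reversed(sets))) == base
        assert jaccard_multi(sets + [sets[0] | {99}]) <= base + 1e-12


class TestRecoveryFloor:
    def test_all_selectors_recover_half_the_signal_at_level_zero(self):
        """On clean labels with d=1.5, every selector keeps >= 50% of the
        truly informative features (sanity floor)."""
        profile = DatasetProfile(
            name="d1strong", n_samples=260, n_features=265, prevalence=0.49,
            n_informative=10, effect_size=1.5, block_size=5, block_rho=0.8,
        )
        ds = generate(profile, seed=31)
        truth = set(ds.truth)
        for name in ("mannwhitney", "rfe", "lasso", "mrmr"):
            res = run_selector(name, ds.features, ds.labels, seed=1)
            recovered = len(truth & set(res.selected)) / len(truth)
            assert recovered >= 0.5, f"{name} recovered only {recovered:.0%}"


def test_default_n_target_rule():
    assert default_n_target(182) == 30
    assert default_n_target(70) == 14
    assert default_n_target(4) == 1
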
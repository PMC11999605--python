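"""Rank-sum statistic, permutation ensembles, p-values and step-down
adjustment, checked against hand computations and brute-force enumeration."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from eicostats.permtest import (
    Contrast,
    Selector,
    build_ensemble,
    ensemble_statistics,
    perm_pvalue,
    rank_sum,
    run_contrast,
    stepdown_adjust,
)


def exhaustive_pvalue_oracle(x, y):
    """Brute-force two-sided permutation p over all C(n, n_x) assignments."""
    pooled = np.concatenate([x, y])
    n, n_x = len(pooled), len(x)
    ranks = rankdata(pooled)
    e = n_x * (n + 1) / 2.0
    obs = abs(rank_sum(x, y) - e)
    hits = total = 0
    for idx in combinations(range(n), n_x):
        w = ranks[list(idx)].sum()
        hits += abs(w - e) >= obs - 1e-12
        total += 1
    return hits / total


class TestRankSum:
    def test_minimum_when_groups_separated(self):
        assert rank_sum([1, 2, 3], [4, 5, 6]) == 6.0  # ranks 1+2+3

    def test_midranks_with_ties(self):
        # pooled {1,1,1,2} -> midranks (2,2,2,4); W of {1,1} = 4
        assert rank_sum([1, 1], [1, 2]) == 4.0

    def test_identical_groups_centre_at_null_expectation(self):
        x = [3.0, 1.0, 2.0]
        w = rank_sum(x, x)
        n_a, n = 3, 6
        assert w == n_a * (n + 1) / 2

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


class TestEnsemble:
    def test_same_seed_identical(self):
        labels = [True] * 10 + [False] * 10
        e1 = build_ensemble(labels, 50, seed=3)
        e2 = build_ensemble(labels, 50, seed=3)
        np.testing.assert_array_equal(e1.assignments, e2.assignments)

    def test_identity_is_row_zero_and_sizes_preserved(self):
        labels = np.array([True, False, True, False, False, True] * 4)
        ens = build_ensemble(labels, 200, seed=0)
        np.testing.assert_array_equal(ens.assignments[0], labels)
        assert (ens.assignments.sum(axis=1) == labels.sum()).all()

    def test_exhaustive_enumerates_all_assignments(self):
        labels = [True] * 3 + [False] * 3
        ens = build_ensemble(labels, 10_000, seed=0, exhaustive_max_n=12)
        assert ens.exhaustive
        assert ens.assignments.shape == (comb(6, 3), 6)
        uniq = {tuple(row) for row in ens.assignments}
        assert len(uniq) == 20
        assert tuple(labels) in uniq

    def test_b_below_one_raises(self):
        with pytest.raises(ValueError):
            build_ensemble([True, False] * 10, 0)


class TestPermPvalue:
    def test_floor_when_observed_most_extreme(self):
        assert perm_pvalue(10.0, np.zeros(99)) == pytest.approx(1 / 100)

    def test_constant_data_gives_p_one(self):
        vals = pd.DataFrame({"m": np.ones(8)})
        res, _ = run_contrast(vals, [True] * 4 + [False] * 4, "c", b=50, seed=1,
                              exhaustive_max_n=0)
        assert res[0].raw_p == 1.0

    def test_separated_groups_exhaustive_example(self):
        vals = pd.DataFrame({"m": [1, 2, 3, 4, 5, 6.0]})
        res, ens = run_contrast(vals, [True] * 3 + [False] * 3, "c", b=10, seed=0)
        assert ens.exhaustive
        assert res[0].raw_p == pytest.approx(2 / 20)  # = 0.1

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 5), (2, 6)])
    def test_exhaustive_equals_bruteforce_oracle(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        x, y = rng.normal(size=n_a), rng.normal(1.0, size=n_b)
        vals = pd.DataFrame({"m": np.concatenate([x, y])})
        res, _ = run_contrast(vals, [True] * n_a + [False] * n_b, "c", b=10, seed=0)
        assert res[0].raw_p == pytest.approx(exhaustive_pvalue_oracle(x, y))

    @pytest.mark.parametrize("n_a,n_b", [(4, 4), (3, 6)])
    def test_exhaustive_matches_scipy_exact_wilcoxon(self, n_a, n_b):
        """With no ties the enumeration equals the exact two-sided
        Mann-Whitney/Wilcoxon p-value (symmetric null)."""
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=n_a), rng.normal(0.5, size=n_b)
        vals = pd.DataFrame({"m": np.concatenate([x, y])})
        res, _ = run_contrast(vals, [True] * n_a + [False] * n_b, "c", b=10, seed=0)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert res[0].raw_p == pytest.approx(expected)

    def test_random_ensemble_converges_to_exhaustive(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=5), rng.normal(0.8, size=5)
        vals = pd.DataFrame({"m": np.concatenate([x, y])})
        labels = [True] * 5 + [False] * 5
        exact = exhaustive_pvalue_oracle(x, y)
        res, _ = run_contrast(vals, labels, "c", b=20_000, seed=11, exhaustive_max_n=0)
        assert res[0].raw_p == pytest.approx(exact, abs=0.01)


class TestStepdownAdjust:
    def counts_for(self, values, labels, b=500, seed=0):
        ens = build_ensemble(labels, b, seed=seed, exhaustive_max_n=0)
        ensemble_statistics(ens, values)
        return ens

    def test_single_hypothesis_adjusted_equals_raw(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame({"m": rng.normal(size=12)})
        res, _ = run_contrast(vals, [True] * 6 + [False] * 6, "c", b=200, seed=2,
                              exhaustive_max_n=0)
        assert res[0].adj_p == pytest.approx(res[0].raw_p)

    def test_all_raw_one_stay_one(self):
        vals = pd.DataFrame({f"m{j}": np.ones(8) for j in range(4)})
        res, _ = run_contrast(vals, [True] * 4 + [False] * 4, "c", b=100, seed=0,
                              exhaustive_max_n=0)
        assert all(r.raw_p == 1.0 and r.adj_p == 1.0 for r in res)

    def test_duplicated_metabolites_adjusted_equals_raw(self):
        """Perfectly correlated hypotheses: the joint min-p null is degenerate
        so minP applies no penalty."""
        rng = np.random.default_rng(3)
        col = rng.normal(size=16) + np.repeat([0.8, 0.0], 8)
        vals = pd.DataFrame({f"m{j}": col for j in range(5)})
        res, _ = run_contrast(vals, [True] * 8 + [False] * 8, "c", b=999, seed=4,
                              exhaustive_max_n=0)
        for r in res:
            assert r.adj_p == pytest.approx(r.raw_p)

    def test_bh_hand_example(self):
        adj = stepdown_adjust([0.01, 0.02, 0.03], method="bh")
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.normal(size=(20, 8)), columns=[f"m{j}" for j in range(8)])
        vals.iloc[:10, 0] += 2.0
        res, _ = run_contrast(vals, [True] * 10 + [False] * 10, "c", b=500, seed=6,
                              exhaustive_max_n=0)
        raw = np.array([r.raw_p for r in res])
        adj = np.array([r.adj_p for r in res])
        assert (adj >= raw - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(raw, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_mismatched_dimensions_raise(self):
        with pytest.raises(ValueError):
            stepdown_adjust([0.1, 0.2], counts=np.zeros((10, 3), dtype=int), method="minp")


class TestRunContrast:
    def test_subject_order_permutation_invariance(self):
        rng = np.random.default_rng(21)
        n = 24
        vals = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"),
                            index=[f"s{i}" for i in range(n)])
        labels = np.array([True] * 12 + [False] * 12)
        res1, _ = run_contrast(vals, labels, "c", b=400, seed=5, exhaustive_max_n=0)
        perm = rng.permutation(n)
        res2, _ = run_contrast(vals.iloc[perm], labels[perm], "c", b=400, seed=5,
                               exhaustive_max_n=0)
        for r1, r2 in zip(res1, res2):
            assert r1.statistic == r2.statistic
            assert r1.raw_p == r2.raw_p

    def test_missing_cells_dropped_pairwise(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame({"full": rng.normal(size=12), "holey": rng.normal(size=12)})
        vals.loc[vals.index[:3], "holey"] = np.nan
        res, _ = run_contrast(vals, [True] * 6 + [False] * 6, "c", b=200, seed=0,
                              exhaustive_max_n=0)
        by_id = {r.metabolite: r for r in res}
        assert by_id["full"].n_a == 6 and by_id["full"].n_b == 6
        assert by_id["holey"].n_a == 3 and by_id["holey"].n_b == 6
        assert 0 < by_id["holey"].raw_p <= 1

    def test_too_few_subjects_raises(self):
        vals = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            run_contrast(vals, [True, False, False], "c", b=10)

    def test_planted_effect_detected_with_correct_direction(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(
            {"null": rng.normal(size=60), "up": np.r_[rng.normal(3.0, 1, 30), rng.normal(0, 1, 30)]}
        )
        res, _ = run_contrast(vals, [True] * 30 + [False] * 30, "c", b=999, seed=1)
        by_id = {r.metabolite: r for r in res}
        assert by_id["up"].raw_p == pytest.approx(1 / 1000)
        assert by_id["up"].direction == 1
        assert by_id["up"].adj_p < by_id["null"].adj_p


class TestContrastSelectors:
    def test_selectors_split_and_validate(self):
        from eicostats.datatypes import SampleMeta

        samples = [
            SampleMeta("c1", "control", False, 6.0),
            SampleMeta("s1", "severe", True, 7.0),
            SampleMeta("s2", "severe", False, 7.0),
        ]
        c = Contrast("ctrl_vs_sev_ocs", Selector("control"), Selector("severe", ocs=True))
        a, b = c.split(samples)
        assert a == ["c1"] and b == ["s1"]
        with pytest.raises(ValueError):
            Contrast("bad", Selector("moderate"), Selector("control")).split(samples)
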
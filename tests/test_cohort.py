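"""Nonparametric stack vs independent enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpnmethane.cohort import (
    compare_groups, kruskal_wallis, pairwise_wilcoxon_bh, shapiro_wilk,
    spearman_screen,
)


def exact_rank_sum_p(x, y, alternative):
    """Full enumeration oracle: distribution of the rank sum of group y
    over all C(n+m, m) assignments of the pooled ranks (tie-free data)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    m = len(y)
    observed = ranks[len(x):].sum()
    sums = [sum(c) for c in combinations(ranks, m)]
    sums = np.array(sums)
    if alternative == "greater":  # y greater -> y's ranks high
        return np.mean(sums >= observed - 1e-9)
    if alternative == "less":
        return np.mean(sums <= observed + 1e-9)
    hi = np.mean(sums >= observed - 1e-9)
    lo = np.mean(sums <= observed + 1e-9)
    return min(1.0, 2 * min(hi, lo))


def hand_H(rank_groups, n):
    """Kruskal-Wallis H from first principles (tie-free ranks)."""
    return 12.0 / (n * (n + 1)) * sum(
        len(g) * (np.mean(g) - (n + 1) / 2.0) ** 2 for g in rank_groups)


def exact_kruskal_p(groups):
    """Enumeration oracle for the permutation p of H (tie-free data):
    walks every split of the pooled ranks into the group sizes, computing
    H from the textbook rank formula."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    obs_groups, i = [], 0
    for s in sizes:
        obs_groups.append(ranks[i:i + s])
        i += s
    H_obs = hand_H(obs_groups, n)

    def splits(remaining, sizes_left):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        k = sizes_left[0]
        for combo in combinations(remaining, k):
            rest = tuple(r for r in remaining if r not in combo)
            for tail in splits(rest, sizes_left[1:]):
                yield (combo,) + tail

    count = total = 0
    for split in splits(tuple(ranks), sizes):
        H = hand_H([np.array(g) for g in split], n)
        count += H >= H_obs - 1e-12
        total += 1
    return count / total


class TestShapiroWilk:
    def test_normal_quantiles_near_one(self):
        q = stats.norm.ppf((np.arange(1, 11) - 0.5) / 10)
        W, _ = shapiro_wilk(q)
        assert W > 0.98

    def test_skewed_data_rejected(self):
        rng = np.random.default_rng(42)
        _, p = shapiro_wilk(rng.exponential(size=50))
        assert p < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(Exception):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([3.0, 3.0, 3.0])


class TestKruskalWallis:
    def test_hand_ranked_two_groups(self):
        H, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert H == pytest.approx(3.857142857, rel=1e-9)
        assert df == 1

    def test_identical_groups_zero(self):
        H, _, p = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert H == 0.0 and p == 1.0

    def test_four_groups_df_3(self):
        _, df, _ = kruskal_wallis([[1, 2], [3, 4], [5, 6], [7, 8]])
        assert df == 3

    def test_chi2_p_matches_statistic(self):
        H, df, p = kruskal_wallis([[1, 5, 9], [2, 6, 10], [3, 7, 11]])
        assert p == pytest.approx(stats.chi2.sf(H, df), rel=1e-12)


class TestPairwiseWilcoxon:
    def test_exact_one_sided_enumeration_value(self):
        # complete separation of 3 vs 3: p = 1 / C(6,3) = 0.05
        out = pairwise_wilcoxon_bh({"a": [1, 2, 3], "b": [4, 5, 6]},
                                   {("b", "a"): "greater"})
        assert out.p_raw.iloc[0] == pytest.approx(0.05, rel=1e-12)

    def test_identical_groups_large_p(self):
        out = pairwise_wilcoxon_bh({"a": [1, 2, 3], "b": [1, 2, 3]},
                                   "two-sided")
        assert out.p_raw.iloc[0] >= 0.5

    def test_bh_step_up_hand_values(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03], rtol=1e-12)

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.permutation(20)[:5].astype(float)
            pool = [v for v in range(20) if v not in x]
            y = rng.permutation(pool)[:6].astype(float)
            out = pairwise_wilcoxon_bh({"x": x, "y": y},
                                       {("x", "y"): alternative})
            oracle = exact_rank_sum_p(y, x, alternative)
            assert out.p_raw.iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i * 0.5, 1, 8)
                  for i, k in enumerate("abcd")}
        out = pairwise_wilcoxon_bh(groups, "two-sided")
        assert (out.p_adj >= out.p_raw - 1e-15).all()
        assert (out.p_adj <= 1.0).all()
        srt = out.sort_values("p_raw")
        assert srt.p_adj.is_monotonic_increasing

    def test_direction_flips_for_reversed_pair(self):
        a, b = [1.0, 2, 3, 4], [5.0, 6, 7, 8]
        p1 = pairwise_wilcoxon_bh({"a": a, "b": b},
                                  {("a", "b"): "less"}).p_raw.iloc[0]
        p2 = pairwise_wilcoxon_bh({"a": a, "b": b},
                                  {("b", "a"): "greater"}).p_raw.iloc[0]
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestKruskalEnumeration:
    @pytest.mark.parametrize("groups", [
        ([1.0, 4.0, 6.0], [2.0, 3.0, 5.0]),
        ([1.0, 2.0, 7.0, 8.0], [3.0, 4.0], [5.0, 6.0, 9.0]),
    ])
    def test_matches_permutation_oracle_small_groups(self, groups):
        """The exact permutation p of H matches a brute-force enumeration
        over raw permutations of the pooled data."""
        from mpnmethane.cohort import kruskal_wallis_permutation_p
        p_pkg = kruskal_wallis_permutation_p(groups)
        p_oracle = exact_kruskal_p([np.asarray(g) for g in groups])
        assert p_pkg == pytest.approx(p_oracle, abs=1e-12)


class TestSpearman:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [10, 20, 30, 40],
                           "c": [4, 3, 2, 1]})
        out = spearman_screen(df)
        rho = {(r.param_a, r.param_b): r.rho for r in out.itertuples()}
        assert rho[("a", "b")] == pytest.approx(1.0)
        assert rho[("a", "c")] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        assert spearman_screen(df).rho.iloc[0] == pytest.approx(0.8)

    def test_too_few_complete_cases_not_estimable(self):
        df = pd.DataFrame({"x": [1, 2, 3, np.nan],
                           "y": [1, np.nan, 2, 4.0]})
        out = spearman_screen(df)
        assert np.isnan(out.rho.iloc[0]) and out.n.iloc[0] == 2


class TestCompareGroups:
    def test_depth_style_comparison(self):
        rng = np.random.default_rng(1)
        groups = {
            "surface": rng.lognormal(np.log(0.4), 0.5, 24),
            "intermediate": rng.lognormal(np.log(0.3), 0.5, 24),
            "DCM": rng.lognormal(np.log(0.07), 0.5, 24),
            "below_DCM": rng.lognormal(np.log(0.06), 0.5, 24),
        }
        res = compare_groups(groups, "two-sided")
        assert res.df == 3
        assert res.p < 0.01
        assert len(res.pairwise) == 6
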
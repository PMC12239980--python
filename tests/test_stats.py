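"""Statistical tests against enumeration, permutation and scipy oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from correaevo.stats import (
    cuzick_trend,
    fisher_exact,
    kruskal_wallis_dunn,
    wilcoxon_rank_sum,
)


def fisher_enumeration_oracle(a, b, c, d):
    """Exact integer-arithmetic two-sided Fisher (point-probability rule)."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c)
    total = sum(math.comb(r1, x) * math.comb(r2, c1 - x)
                for x in range(lo, hi + 1)
                if math.comb(r1, x) * math.comb(r2, c1 - x) <= num_obs)
    return total / math.comb(a + b + c + d, c1)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ([[6, 8], [2, 23]], 0.016),   # TP53 mutant vs outcome
        ([[7, 7], [2, 23]], 0.005),   # PRKDC positive vs outcome
        ([[4, 10], [3, 22]], 0.225),  # PCLO positive vs outcome
    ])
    def test_validation_cohort_golden_values(self, table, expected):
        assert round(fisher_exact(table), 3) == expected

    def test_five_vs_zero_of_fourteen_contrast(self):
        # the 35.7% vs 0% stage contrast; two-sided point-probability value
        assert fisher_exact([[5, 9], [0, 14]]) == pytest.approx(
            fisher_enumeration_oracle(5, 9, 0, 14), abs=1e-12)

    @pytest.mark.parametrize("a,b", [(3, 11), (1, 1), (0, 5), (7, 2)])
    def test_identical_rows_give_p_one(self, a, b):
        assert fisher_exact([[a, b], [a, b]]) == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b + c + d == 0:
                continue
            ours = fisher_exact([[a, b], [c, d]])
            oracle = fisher_enumeration_oracle(int(a), int(b), int(c), int(d))
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_matches_scipy_two_sided(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                sps.fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])


def rank_sum_enumeration_oracle(x, y):
    """Full permutation enumeration of the rank-sum two-sided p."""
    pooled = list(x) + list(y)
    ranks = sps.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    ws = [sum(ranks[list(c)]) for c in
          itertools.combinations(range(len(pooled)), n)]
    total = len(ws)
    lower = sum(w <= w_obs + 1e-12 for w in ws)
    higher = sum(w >= w_obs - 1e-12 for w in ws)
    return min(1.0, 2.0 * min(lower, higher) / total)


class TestWilcoxon:
    def test_separated_small_groups(self):
        # {1,2,3} vs {10,11,12}: most extreme of C(6,3)=20 assignments
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n, m = rng.integers(2, 7, size=2)
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.uniform(-1, 1), size=m)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                rank_sum_enumeration_oracle(x, y), abs=1e-12)

    def test_large_sample_tracks_scipy_normal_approximation(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(loc=0.5, size=35)
        ours = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestKruskalDunn:
    def test_identical_constant_groups_flagged_degenerate(self):
        res = kruskal_wallis_dunn([[5.0] * 4, [5.0] * 4, [5.0] * 4])
        assert res.degenerate
        assert res.h == 0.0
        assert res.p_global == 1.0

    def test_h_matches_scipy_with_ties(self, rng):
        groups = [list(rng.integers(0, 6, size=8)) for _ in range(4)]
        res = kruskal_wallis_dunn(groups)
        ref_h, ref_p = sps.kruskal(*groups)
        assert res.h == pytest.approx(ref_h, rel=1e-10)
        assert res.p_global == pytest.approx(ref_p, rel=1e-10)

    def test_separated_groups_all_pairs_significant(self):
        # pooled-rank Dunn z needs ~10/group before adjacent pairs can
        # reach significance, however separated the values are
        groups = [[i + shift for i in range(10)]
                  for shift in (0, 100, 200)]
        res = kruskal_wallis_dunn(groups)
        assert res.p_global < 0.01
        assert (res.pairwise["p_raw"] < 0.05).all()

    def test_only_shifted_group_pairs_significant(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        shifted = [x + 50 for x in base]
        res = kruskal_wallis_dunn([base, [x + 0.01 for x in base], shifted])
        pw = res.pairwise
        involving_shift = pw[(pw.group_a == 2) | (pw.group_b == 2)]
        not_involving = pw[(pw.group_a != 2) & (pw.group_b != 2)]
        assert (involving_shift["p_raw"] < 0.05).all()
        assert (not_involving["p_raw"] > 0.5).all()

    def test_adjustment_never_decreases_p(self, rng):
        groups = [list(rng.normal(loc=i, size=6)) for i in range(4)]
        raw = kruskal_wallis_dunn(groups, adjust="none").pairwise
        holm = kruskal_wallis_dunn(groups, adjust="holm").pairwise
        assert (holm["p_adjusted"].to_numpy()
                >= raw["p_raw"].to_numpy() - 1e-12).all()

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1, 2], [3, 4]])


def cuzick_permutation_oracle(groups, n_perm, seed):
    """Monte-Carlo permutation p-value for the trend statistic T."""
    rng = np.random.default_rng(seed)
    scores = np.concatenate([np.full(len(g), i + 1)
                             for i, g in enumerate(groups)])
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = sps.rankdata(pooled)
    t_obs = float((scores * ranks).sum())
    ts = np.empty(n_perm)
    for i in range(n_perm):
        ts[i] = float((scores * rng.permutation(ranks)).sum())
    # two-sided via distance from the permutation mean
    centre = ts.mean()
    return float((np.abs(ts - centre) >= abs(t_obs - centre) - 1e-9).mean())


class TestCuzickTrend:
    def test_perfect_trend_detected(self):
        groups = [[i + shift for i in range(10)] for shift in (0, 5, 10, 15)]
        res = cuzick_trend(groups)
        assert res.z > 0
        assert res.p < 0.05

    def test_reversing_order_flips_sign(self, rng):
        groups = [list(rng.normal(loc=i, size=7)) for i in range(4)]
        res = cuzick_trend(groups)
        rev = cuzick_trend(groups[::-1])
        assert rev.z == pytest.approx(-res.z, abs=1e-10)
        assert rev.p == pytest.approx(res.p, abs=1e-10)

    def test_small_data_matches_permutation_oracle(self):
        groups = [[1.2, 0.8, 1.5, 1.1], [1.6, 1.9, 1.4, 2.0],
                  [2.4, 2.1, 2.8, 2.2]]
        res = cuzick_trend(groups, method="exact")
        p_mc = cuzick_permutation_oracle(groups, n_perm=100_000, seed=1)
        se = math.sqrt(max(p_mc, 1e-4) * (1 - p_mc) / 1e5)
        assert res.p == pytest.approx(p_mc, abs=4 * se + 1e-4)

    def test_exact_and_normal_methods_agree_roughly(self):
        groups = [[1.0, 2.0, 1.5, 1.2], [1.8, 1.1, 2.2, 1.6],
                  [2.0, 1.4, 2.5, 1.9]]
        exact = cuzick_trend(groups, method="exact").p
        normal = cuzick_trend(groups, method="normal").p
        assert abs(exact - normal) < 0.02

    def test_exact_method_refuses_large_samples(self):
        groups = [list(range(20)) for _ in range(4)]
        with pytest.raises(ValueError, match="arrangements"):
            cuzick_trend(groups, method="exact")

    def test_all_equal_observations_flagged_degenerate(self):
        res = cuzick_trend([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.degenerate and res.p == 1.0

    def test_custom_scores_change_weighting(self):
        groups = [[1, 2, 3], [4, 5, 6], [2, 3, 4]]
        default = cuzick_trend(groups)
        weighted = cuzick_trend(groups, scores=[1, 10, 11])
        assert default.z != pytest.approx(weighted.z)

    def test_null_type_one_error_controlled(self):
        """Under the null (one common distribution), rejects at <= 6%."""
        rng = np.random.default_rng(2024)
        n_reps, alpha = 600, 0.05
        rejections = 0
        for _ in range(n_reps):
            groups = [rng.normal(size=14) for _ in range(4)]
            if cuzick_trend(groups).p < alpha:
                rejections += 1
        assert rejections / n_reps <= 0.06 + 2 * math.sqrt(0.05 * 0.95 / n_reps)
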
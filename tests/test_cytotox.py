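"""Cytotoxicity percentages and exact nonparametric statistics."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import kruskal, mannwhitneyu, rankdata

from allofoot.cytotox import (
    CytotoxicityTable,
    cytotoxicity_percent,
    dunns_test,
    exact_mann_whitney,
    kruskal_wallis,
)


class TestCytotoxicityPercent:
    @pytest.mark.parametrize("exp, base, mx, expected", [
        (0.30, 0.10, 0.90, 25.0),
        (0.10, 0.10, 0.90, 0.0),
        (0.90, 0.10, 0.90, 100.0),
        (0.05, 0.10, 0.90, -6.25),   # below-baseline reported as-is
    ])
    def test_formula(self, exp, base, mx, expected):
        assert cytotoxicity_percent(exp, base, mx) == pytest.approx(expected)

    def test_maximum_must_exceed_baseline(self):
        with pytest.raises(ValueError):
            cytotoxicity_percent(0.5, 0.9, 0.9)

    def test_invariant_to_common_count_scaling(self):
        # gated counts scaled by any common total give the same percentage
        dead = {"exp": 300, "base": 100, "max": 900}
        for total in (1000, 5000, 12345):
            pct = cytotoxicity_percent(dead["exp"] / total, dead["base"] / total,
                                       dead["max"] / total)
            assert pct == pytest.approx(25.0)

    def test_table_validation(self):
        with pytest.raises(ValueError, match="maximum"):
            CytotoxicityTable("bad", [(0.5, 0.9, 0.8)])
        with pytest.raises(ValueError, match="fraction"):
            CytotoxicityTable("bad", [(1.5, 0.1, 0.9)])
        table = CytotoxicityTable("ok", [(0.3, 0.1, 0.9), (0.5, 0.1, 0.9)])
        assert table.cytotoxicity() == pytest.approx([25.0, 50.0])


class TestExactMannWhitney:
    def test_complete_separation_four_vs_four(self):
        r = exact_mann_whitney([1, 2, 3, 4], [5, 6, 7, 8])
        assert r.exact
        assert r.p_value == pytest.approx(2 / 70)
        assert r.p_value == pytest.approx(0.0286, abs=5e-5)

    def test_complete_separation_three_vs_three(self):
        r = exact_mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.p_value == pytest.approx(2 / 20)

    def test_identical_single_values_give_p_one(self):
        assert exact_mann_whitney([5.0], [5.0]).p_value == 1.0

    def test_symmetry_in_sample_order(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=4), rng.normal(size=5)
        assert exact_mann_whitney(x, y).p_value == pytest.approx(
            exact_mann_whitney(y, x).p_value)

    def test_exhaustive_agreement_with_scipy_exact_distribution(self):
        """Exact enumeration equals scipy's exact Mann-Whitney for every
        sample-size pair with n1+n2 <= 12 (tie-free data)."""
        rng = np.random.default_rng(99)
        for n1 in range(1, 7):
            for n2 in range(1, 13 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                ours = exact_mann_whitney(x, y).p_value
                ref = mannwhitneyu(x, y, method="exact").pvalue
                assert ours == pytest.approx(ref, abs=1e-12), (n1, n2)

    def test_tied_data_matches_inline_enumeration(self):
        # independent oracle: enumerate the permutation distribution directly
        x, y = [1.0, 1.0, 2.0, 3.0], [2.0, 2.0, 3.0, 4.0]
        pooled = np.array(x + y)
        ranks = rankdata(pooled)
        n1 = len(x)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = [ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
              for idx in combinations(range(len(pooled)), n1)]
        us = np.array(us)
        p_oracle = min(1.0, 2 * min(np.mean(us <= u_obs + 1e-9), np.mean(us >= u_obs - 1e-9)))
        assert exact_mann_whitney(x, y).p_value == pytest.approx(p_oracle)

    def test_null_rejection_rate_at_most_alpha(self):
        """Under a shared continuous null the exact test at alpha = 0.05
        rejects at the attainable level (p = 2/70 for 4 vs 4)."""
        rng = np.random.default_rng(1234)
        n_sim = 10_000
        rejections = 0
        for _ in range(n_sim):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            if exact_mann_whitney(x, y).p_value <= 0.05:
                rejections += 1
        rate = rejections / n_sim
        attainable = 2 / 70
        se = math.sqrt(attainable * (1 - attainable) / n_sim)
        assert rate <= 0.05
        assert abs(rate - attainable) <= 3 * se

    def test_large_samples_fall_back_to_normal_approximation(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=15), rng.normal(1.0, size=15)
        r = exact_mann_whitney(x, y)
        assert not r.exact
        assert 0.0 <= r.p_value <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            exact_mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_give_h_zero_p_one(self):
        r = kruskal_wallis([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_h_for_three_pairs(self):
        # ranks 1..6; rank sums 3, 7, 11 -> H = 12/(6*7) * sum(R^2/n) - 3*7
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        expected_h = 12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21
        assert r.statistic == pytest.approx(expected_h)

    def test_matches_scipy_with_ties(self):
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0, 5.0], [4.0, 4.0, 6.0, 7.0]]
        r = kruskal_wallis(groups)
        ref = kruskal(*groups)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_chi_square_p_close_to_permutation_p(self):
        """The chi-square approximation tracks the permutation-exact p
        within Monte-Carlo error on small groups."""
        groups = [[1.0, 4.0, 6.0], [2.0, 7.0, 9.0], [8.0, 10.0, 12.0]]
        r = kruskal_wallis(groups)
        rng = np.random.default_rng(7)
        pooled = np.concatenate(groups)
        sizes = np.array([len(g) for g in groups])
        n = len(pooled)
        ranks = rankdata(pooled)
        n_draws = 100_000
        # permuting the data is equivalent to permuting the fixed rank multiset
        perm_ranks = ranks[np.argsort(rng.random((n_draws, n)), axis=1)]
        bounds = np.cumsum(sizes)[:-1]
        h = np.zeros(n_draws)
        start = 0
        for s in sizes:
            h += perm_ranks[:, start:start + s].sum(axis=1) ** 2 / s
            start += s
        h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)  # tie-free data: no correction
        p_perm = float(np.mean(h >= r.statistic - 1e-12))
        se = math.sqrt(p_perm * (1 - p_perm) / n_draws)
        assert abs(r.p_value - p_perm) < max(5 * se, 0.02)

    def test_group_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestDunn:
    def test_identical_groups_all_p_one(self):
        res = dunns_test([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert all(r.p_value == 1.0 for r in res.values())

    def test_most_separated_pair_has_smallest_p(self):
        groups = [[10.0, 11.0, 12.0], [10.5, 11.5, 12.5],
                  [11.0, 12.0, 13.0], [40.0, 41.0, 42.0]]
        res = dunns_test(groups, labels=["a", "b", "c", "d"])
        best = min(res, key=lambda k: res[k].p_value)
        assert "d" in best and "a" in best

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(m, 1.0, size=4) for m in (0.0, 0.5, 2.0, 3.0)]
        for r in dunns_test(groups).values():
            assert r.p_value >= r.detail["p_unadjusted"] - 1e-12

    def test_holm_adjustment_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1.0, size=4) for m in (0.0, 1.0, 2.0)]
        bonf = dunns_test(groups, adjustment="bonferroni")
        holm = dunns_test(groups, adjustment="holm")
        for pair in bonf:
            assert holm[pair].p_value <= bonf[pair].p_value + 1e-12
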
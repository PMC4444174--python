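"""G statistic, Williams correction, Monte-Carlo null, post-hoc tests,
Spearman and Kruskal-Wallis, each against an independent oracle."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from movelead.inference import (
    g_statistic,
    holm_adjust,
    kruskal_wallis,
    mc_uniform_test,
    posthoc_chance_tests,
    spearman,
    williams_correct,
)

BO_DEP = [6, 2, 11, 0, 8, 0, 1, 0, 0, 0, 0, 0]
AD_FRONT = [1, 5, 4, 11, 0, 0]
BO_AGES = [16, 8, 15, 4, 5, 4, 2, 2, 1, 1, 1, 1]
BO_FRONT = [2, 0, 3, 0, 5, 1, 0, 0, 0, 0, 0, 0]
BO_PRE = [5, 3, 8, 5, 13, 6, 1, 4, 6, 4, 8, 3]


def g_oracle(counts):
    """Term-by-term evaluation of 2*sum(o*ln(o/e)) with uniform expected."""
    n, k = sum(counts), len(counts)
    total = 0.0
    for o in counts:
        if o > 0:
            total += o * math.log(o / (n / k))
    return 2.0 * total


class TestGStatistic:
    @pytest.mark.parametrize("counts", [BO_DEP, AD_FRONT, BO_PRE, [3, 3, 3]])
    def test_matches_term_by_term_oracle(self, counts):
        n, k = sum(counts), len(counts)
        got = g_statistic(counts, [n / k] * k)
        assert got == pytest.approx(g_oracle(counts), rel=1e-12)

    def test_frozen_oracle_values(self):
        # hand-summed: BO departures 62.85, AD front 27.32
        assert g_statistic(BO_DEP, [28 / 12] * 12) == pytest.approx(62.85, abs=0.01)
        assert g_statistic(AD_FRONT, [21 / 6] * 6) == pytest.approx(27.32, abs=0.01)

    def test_counts_equal_expected_gives_zero(self):
        assert g_statistic([5, 5, 5], [5, 5, 5]) == pytest.approx(0.0)

    def test_all_zero_counts_undefined(self):
        assert g_statistic([0, 0, 0], [1, 1, 1]) is None

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="total"):
            g_statistic([5, 5], [3, 3])


class TestWilliams:
    def test_small_sample_factor(self):
        q, g_adj = williams_correct(62.85, 28, 12)
        assert q == pytest.approx(1.0774, abs=1e-4)
        assert g_adj == pytest.approx(58.3, abs=0.05)

    def test_ad_front_value(self):
        g = g_statistic(AD_FRONT, [21 / 6] * 6)
        _, g_adj = williams_correct(g, 21, 6)
        assert g_adj == pytest.approx(25.9, abs=0.05)

    def test_correction_vanishes_asymptotically(self):
        q, g_adj = williams_correct(10.0, 1e12, 12)
        assert q == pytest.approx(1.0, abs=1e-9)
        assert g_adj == pytest.approx(10.0, abs=1e-6)

    @given(st.integers(5, 500), st.integers(2, 20))
    def test_q_strictly_above_one_for_finite_n(self, n, k):
        q, g_adj = williams_correct(5.0, n, k)
        assert q > 1.0
        assert g_adj < 5.0


class TestMonteCarlo:
    def test_extreme_counts_give_tiny_p(self):
        res = mc_uniform_test(BO_DEP, B=2000, seed=0)
        assert res.p_mc < 0.001
        assert res.df == 11
        assert res.G_adj == pytest.approx(58.3, abs=0.05)

    def test_uniform_counts_give_large_p(self):
        for seed in (0, 1, 2):
            res = mc_uniform_test([5] * 12, B=2000, seed=seed)
            assert res.p_mc >= 0.5

    def test_near_threshold_counts_land_in_band(self):
        # G_adj ~ 18.2 on 11 df sits near p = 0.078
        for seed in (0, 1, 2):
            res = mc_uniform_test(BO_PRE, B=2000, seed=seed)
            assert 0.05 < res.p_mc < 0.12

    def test_p_never_zero_and_seed_reproducible(self):
        a = mc_uniform_test(BO_DEP, B=200, seed=9)
        b = mc_uniform_test(BO_DEP, B=200, seed=9)
        assert a == b
        assert a.p_mc >= 1 / 201

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            mc_uniform_test(BO_DEP, B=0, seed=0)


class TestPosthoc:
    def test_bo_departures_flag_counts_eleven_and_eight(self):
        res = posthoc_chance_tests(BO_DEP, n=28)
        above = {t.observed for t in res.tests if t.significant}
        assert above == {11, 8}
        assert all(t.direction == "above" for t in res.tests if t.significant)

    def test_equal_counts_flag_nothing(self):
        res = posthoc_chance_tests([4] * 6, n=24)
        assert res.flagged == ()

    def test_monopoly_matches_exact_binomial_enumeration(self):
        # one individual holds all n=20 of k=5; oracle: two-sided exact
        # binomial p sums P(x) over outcomes no more likely than observed
        from scipy.stats import binom

        res = posthoc_chance_tests([20, 0, 0, 0, 0], n=20)
        assert res.tests[0].significant and res.tests[0].direction == "above"
        pmf = binom.pmf(np.arange(21), 20, 0.2)
        assert res.tests[0].p_raw == pytest.approx(
            pmf[pmf <= pmf[20] * (1 + 1e-9)].sum(), rel=1e-9
        )
        assert res.tests[1].p_raw == pytest.approx(
            pmf[pmf <= pmf[0] * (1 + 1e-9)].sum(), rel=1e-9
        )
        assert all(t.direction == "below" for t in res.tests[1:])

    def test_holm_dominates_raw(self):
        res = posthoc_chance_tests(BO_DEP, n=28)
        assert all(t.p_holm >= t.p_raw - 1e-15 for t in res.tests)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_executed_step_down(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones_stay_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_monotone_in_sorted_order_and_permutation_equivariant(self, ps):
        adj = holm_adjust(ps)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.roll(np.arange(len(ps)), 1)
        adj_perm = holm_adjust(list(np.asarray(ps)[perm]))
        assert adj_perm == pytest.approx(adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


def spearman_oracle(x, y):
    """Pure-python mid-rank Spearman with full permutation p (n <= 6)."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    def pearson(a, b):
        n = len(a)
        ma, mb = sum(a) / n, sum(b) / n
        num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
        da = math.sqrt(sum((ai - ma) ** 2 for ai in a))
        db = math.sqrt(sum((bi - mb) ** 2 for bi in b))
        if da == 0 or db == 0:
            return None
        return num / (da * db)

    rx, ry = midranks(x), midranks(y)
    rs = pearson(rx, ry)
    if rs is None:
        return None, None
    hits = total = 0
    for perm in permutations(ry):
        r = pearson(rx, list(perm))
        total += 1
        if abs(r) >= abs(rs) - 1e-12:
            hits += 1
    return rs, hits / total


class TestSpearman:
    def test_bo_age_departure_correlation(self):
        rs, p = spearman(BO_AGES, BO_DEP)
        assert rs == pytest.approx(0.80, abs=0.005)
        assert p < 0.01

    def test_bo_age_front_correlation(self):
        rs, _ = spearman(BO_AGES, BO_FRONT)
        assert rs == pytest.approx(0.70, abs=0.005)

    def test_identity_without_ties_is_one(self):
        rs, p = spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert rs == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_zero_variance_undefined(self):
        assert spearman([1, 1, 1], [1, 2, 3]) == (None, None)

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=6),
        st.data(),
    )
    def test_matches_brute_force_oracle(self, x, data):
        y = data.draw(st.lists(st.integers(0, 5), min_size=len(x), max_size=len(x)))
        expect = spearman_oracle(x, y)
        got = spearman(x, y)
        if expect[0] is None:
            assert got == (None, None)
        else:
            assert got[0] == pytest.approx(expect[0], abs=1e-12)
            assert got[1] == pytest.approx(expect[1], abs=1e-12)


def kw_oracle(groups):
    """Direct rank-sum formula with tie correction."""
    flat = [v for g in groups for v in g]
    order = sorted(range(len(flat)), key=lambda i: flat[i])
    ranks = [0.0] * len(flat)
    i = 0
    while i < len(flat):
        j = i
        while j + 1 < len(flat) and flat[order[j + 1]] == flat[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    n = len(flat)
    pos = 0
    h = 0.0
    for g in groups:
        r = sum(ranks[pos : pos + len(g)])
        h += r * r / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in flat:
        ties[v] = ties.get(v, 0) + 1
    c = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / c


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        assert kruskal_wallis([[3, 3, 3], [3, 3]]) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "groups",
        [
            [[1, 2, 3], [4, 5, 6]],
            [[1, 1, 2], [2, 3, 3], [4]],
            [[10, 20], [20, 30], [5, 5, 40]],
        ],
    )
    def test_matches_direct_formula(self, groups):
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_oracle(groups), rel=1e-9)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 500
        for _ in range(reps):
            groups = [rng.exponential(400.0, size=s) for s in (6, 11, 8)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.02
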
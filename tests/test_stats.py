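"""Unit and property tests for the statistical primitives.

Exact rank tests are checked against brute-force enumeration oracles and
against scipy on tie-free inputs; BH against statsmodels. scipy and
statsmodels are used only as independent cross-checks, never as the
implementation.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from refstab.stats import (
    TINY_P,
    bh_adjust,
    kruskal_dunn,
    pairwise_t_pvalues,
    two_sample_t,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

finite_floats = st.floats(-50, 50, allow_nan=False)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestTwoSampleT:
    def test_identical_groups_give_p_one(self):
        r = two_sample_t([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_textbook_pooled_example(self):
        # hand evaluation: means 5 and 6, pooled variance 0.01, df 4
        r = two_sample_t([4.9, 5.0, 5.1], [5.9, 6.0, 6.1], flavor="pooled")
        assert r.statistic == pytest.approx(-12.247, abs=1e-3)
        assert r.df == 4
        assert r.p_value == pytest.approx(2 * sps.t.sf(12.247448, 4), rel=1e-5)

    @pytest.mark.parametrize("flavor", ["pooled", "welch"])
    def test_matches_scipy(self, flavor):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(2, 12))
            y = rng.normal(0.4, 2.0, rng.integers(2, 12))
            mine = two_sample_t(x, y, flavor=flavor)
            ref = sps.ttest_ind(x, y, equal_var=(flavor == "pooled"))
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_variance_conventions(self):
        equal = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert equal.p_value == 1.0 and "degenerate" in equal.flags
        shifted = two_sample_t([2.0, 2.0], [3.0, 3.0])
        assert shifted.p_value == TINY_P and "zero_variance" in shifted.flags
        assert math.isinf(shifted.statistic) and shifted.statistic < 0

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.lists(finite_floats, min_size=2, max_size=8),
        y=st.lists(finite_floats, min_size=2, max_size=8),
    )
    def test_swap_symmetry(self, x, y):
        a, b = two_sample_t(x, y), two_sample_t(y, x)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12) or (
            a.statistic == 0 and b.statistic == 0
        )

    def test_vectorized_pairwise_matches_scalar(self):
        rng = np.random.default_rng(11)
        values = rng.normal(8, 1, size=(40, 12))
        cols = [np.arange(0, 4), np.arange(4, 8), np.arange(8, 12)]
        for flavor in ("pooled", "welch"):
            p = pairwise_t_pvalues(values, cols, flavor=flavor)
            for row in (0, 17, 39):
                expected = [
                    two_sample_t(values[row, a], values[row, b], flavor=flavor).p_value
                    for a, b in itertools.combinations(cols, 2)
                ]
                assert p[row] == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),  # step-up by hand
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.2], [0.2]),
        ],
    )
    def test_known_values(self, raw, expected):
        assert bh_adjust(raw) == pytest.approx(expected)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1, 200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(ref, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-9, 1.0, allow_nan=False), min_size=1, max_size=30))
    def test_never_decreases_and_preserves_order(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        # step-up adjustment preserves the ranking of the raw p-values
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_rank_sum_p(x, y):
    """Enumerate all C(n, nx) group assignments of the pooled midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    sums = np.array([sum(c) for c in itertools.combinations(ranks, nx)])
    lower = np.mean(sums <= w_obs + 1e-9)
    upper = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


def brute_force_signed_rank_p(before, after):
    """Enumerate all 2^n sign assignments of the midranked |differences|."""
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        sums.append(sum(r for s, r in zip(signs, ranks) if s))
    sums = np.array(sums)
    lower = np.mean(sums <= w_obs + 1e-9)
    upper = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_extreme_separation(self):
        # 2 of the 20 equally likely rank assignments are this extreme
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert r.p_value == pytest.approx(0.1)

    def test_identical_degenerate(self):
        r = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            x = rng.integers(0, 4, rng.integers(2, 6)).astype(float)
            y = rng.integers(0, 4, rng.integers(2, 6)).astype(float)
            if np.all(np.concatenate([x, y]) == x[0]):
                continue
            mine = wilcoxon_rank_sum(x, y, mode="exact").p_value
            assert mine == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_tie_free(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            x = rng.permutation(20)[: rng.integers(2, 7)].astype(float)
            pool = np.setdiff1d(np.arange(20, 40), x)
            y = rng.permutation(pool)[: rng.integers(2, 7)].astype(float)
            y = y + rng.uniform(0.01, 0.4)  # guarantee no cross-group ties
            mine = wilcoxon_rank_sum(x, y, mode="exact").p_value
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_normal_close_to_exact(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
            approx = wilcoxon_rank_sum(x, y, mode="normal").p_value
            assert abs(exact - approx) < 0.03

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestSignedRank:
    def test_uniform_shift_six_pairs(self):
        # most extreme one-sided table among 2^6 sign patterns
        before = np.arange(6, dtype=float)
        r = wilcoxon_signed_rank(before, before + 1.0)
        assert r.p_value == pytest.approx(2 / 64)

    def test_no_change_degenerate(self):
        before = np.arange(5, dtype=float)
        r = wilcoxon_signed_rank(before, before)
        assert r.p_value == 1.0 and "degenerate" in r.flags

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(31)
        before = rng.normal(size=10)
        after = before + rng.normal(0.3, 1, 10)
        a = wilcoxon_signed_rank(before, after).p_value
        b = wilcoxon_signed_rank(after, before).p_value
        assert a == pytest.approx(b)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(32)
        for _ in range(30):
            n = rng.integers(3, 9)
            before = rng.normal(size=n)
            after = before + rng.normal(0.2, 1, n)
            mine = wilcoxon_signed_rank(before, after, mode="exact").p_value
            assert mine == pytest.approx(brute_force_signed_rank_p(before, after), abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(33)
        for _ in range(15):
            n = int(rng.integers(5, 12))
            before = rng.normal(size=n)
            after = before + rng.normal(0.5, 1, n)
            mine = wilcoxon_signed_rank(before, after, mode="exact").p_value
            ref = sps.wilcoxon(after, before, mode="exact").pvalue
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

class TestKruskalDunn:
    def test_identical_groups(self):
        omni, pairwise = kruskal_dunn([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert omni.statistic == pytest.approx(0.0)
        assert omni.p_value == pytest.approx(1.0)
        for r in pairwise.values():
            assert r.p_value == pytest.approx(1.0)

    def test_separated_groups_h(self):
        # H on ranks 1..9 split into perfectly ordered thirds
        omni, _ = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert omni.statistic == pytest.approx(7.2, abs=0.01)
        assert omni.df == 2

    def test_matches_scipy_kruskal(self):
        rng = np.random.default_rng(41)
        groups = [rng.normal(loc, 1, 9) for loc in (0, 0.5, 1.0)]
        omni, _ = kruskal_dunn(groups)
        ref = sps.kruskal(*groups)
        assert omni.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert omni.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_relabeling_permutes_pairings(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(loc, 1, 6) for loc in (0, 1, 2)]
        _, fwd = kruskal_dunn(groups)
        _, rev = kruskal_dunn(groups[::-1])
        # pairing (i, j) on reversed input corresponds to (2-j, 2-i)
        for (i, j), r in fwd.items():
            assert rev[(2 - j, 2 - i)].p_value == pytest.approx(r.p_value)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="wilcoxon_rank_sum"):
            kruskal_dunn([[1, 2], [3, 4]])
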
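"""Statistical primitives against brute-force enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from occutail.core_stats import (
    bh_fdr,
    box_summary,
    fisher_r_to_z_compare,
    hypergeometric_enrichment,
    ks_two_sample,
    mann_whitney_u,
    spearman,
)
from oracles import (
    bh_naive,
    hypergeom_upper_naive,
    ks_exact_p_naive,
    ks_statistic_naive,
    mw_exact_p_naive,
    spearman_naive,
)

rng = np.random.default_rng(20240917)

small_pairs = [
    ([1, 3], [2, 4]),
    ([1, 2, 3], [4, 5]),
    ([1, 1, 2], [2, 3, 3]),  # ties across and within groups
    ([0.5, 0.5], [0.5, 1.0]),
    ([1, 2, 3, 4], [2, 3, 5, 6]),
    ([-1, 0, 1], [-2, 0, 2]),
]


class TestKS:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            ks_two_sample([], [1, 2])

    @pytest.mark.parametrize("a,b", small_pairs)
    def test_exact_p_matches_enumeration(self, a, b):
        res = ks_two_sample(a, b, method="exact")
        assert res.statistic == pytest.approx(ks_statistic_naive(a, b))
        assert res.p_value == pytest.approx(ks_exact_p_naive(a, b))

    @given(st.integers(0, 2**32 - 1))
    def test_group_permutation_and_swap_invariance(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=8)
        b = r.normal(size=6)
        base = ks_two_sample(a, b)
        shuffled = ks_two_sample(r.permutation(a), r.permutation(b))
        swapped = ks_two_sample(b, a)
        assert shuffled.statistic == pytest.approx(base.statistic)
        assert shuffled.p_value == pytest.approx(base.p_value)
        assert swapped.statistic == pytest.approx(base.statistic)
        assert swapped.p_value == pytest.approx(base.p_value)


class TestMannWhitney:
    def test_symmetric_null(self):
        a = [1.0, 2.5, 3.5, 7.0]
        res = mann_whitney_u(a, a)
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("a,b", small_pairs)
    def test_exact_p_matches_enumeration(self, a, b):
        res = mann_whitney_u(a, b, method="exact")
        assert res.p_value == pytest.approx(mw_exact_p_naive(a, b))

    def test_paired_all_zero_differences(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3], paired=True)
        assert res.p_value == 1.0

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal-length"):
            mann_whitney_u([1, 2, 3], [1, 2], paired=True)

    def test_paired_detects_consistent_shift(self):
        x = rng.normal(size=40)
        res = mann_whitney_u(x + 1.0, x, paired=True)
        assert res.p_value < 1e-6


class TestSpearman:
    def test_reversal(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_identity(self):
        assert spearman([1, 2, 3], [1, 2, 3]).rho == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3, 4], [1, 2, 4, 3]),
            ([1, 1, 2, 3], [4, 4, 2, 1]),  # ties
            ([5, 1, 1, 2, 9], [3, 3, 3, 1, 0]),
        ],
    )
    def test_matches_rank_then_pearson_oracle(self, x, y):
        assert spearman(x, y).rho == pytest.approx(spearman_naive(x, y))

    def test_constant_vector_flagged(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert not res.defined
        assert math.isnan(res.rho)

    def test_exact_p_agrees_with_permutation_tail(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        res = spearman(x, y, method="exact")
        # enumeration is small enough to redo inline
        from itertools import permutations

        obs = abs(spearman_naive(x, y))
        hits = sum(
            abs(spearman_naive(x, list(p))) >= obs - 1e-12 for p in permutations(y)
        )
        assert res.p_value == pytest.approx(hits / math.factorial(5))

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=12)
        y = r.normal(size=12)
        base = spearman(x, y)
        transformed = spearman(np.exp(x), 3.0 * y + 1.0)
        assert transformed.rho == pytest.approx(base.rho)


class TestFisherRtoZ:
    def test_equal_correlations(self):
        res = fisher_r_to_z_compare(0.5, 100, 0.5, 100)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_strongly_different_correlations(self):
        # the weak vs strong bound-vs-total tail correlations at study-scale n
        res = fisher_r_to_z_compare(0.26, 3000, 0.89, 3000)
        assert res.p_value < 1e-15

    def test_zero_correlations(self):
        assert fisher_r_to_z_compare(0.0, 50, 0.0, 50).p_value == pytest.approx(1.0)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_to_z_compare(1.0, 100, 0.5, 100)


class TestHypergeometric:
    def test_saturated(self):
        assert hypergeometric_enrichment(5, 5, 5, 5) == pytest.approx(1.0)

    def test_complete_overlap_small_universe(self):
        assert hypergeometric_enrichment(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_no_hits(self):
        assert hypergeometric_enrichment(0, 4, 0, 10) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(4, 3, 5, 10)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_combinatorial_sum_on_small_universes(self, seed):
        r = np.random.default_rng(seed)
        background = int(r.integers(4, 16))
        set_size = int(r.integers(1, background + 1))
        hits_total = int(r.integers(0, background + 1))
        lo = max(0, set_size + hits_total - background)
        k = int(r.integers(lo, min(set_size, hits_total) + 1))
        assert hypergeometric_enrichment(k, set_size, hits_total, background) == pytest.approx(
            hypergeom_upper_naive(k, set_size, hits_total, background)
        )


class TestBH:
    def test_single_p(self):
        assert bh_fdr([0.01]) == pytest.approx([0.01])

    def test_step_up_collapses_to_max(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_step_up_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(size=12)
        assert bh_fdr(p) == pytest.approx(bh_naive(list(p)))

    @given(st.integers(0, 2**32 - 1))
    def test_never_decreases_and_preserves_order(self, seed):
        p = np.random.default_rng(seed).uniform(size=15)
        q = bh_fdr(p)
        assert np.all(q >= p)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_idempotent_on_flat_vectors(self):
        q = bh_fdr([0.03, 0.03, 0.03])
        assert bh_fdr(q) == pytest.approx(q)


def test_box_summary_matches_sorted_list_oracle():
    v = rng.normal(size=101)
    s = box_summary(v)
    assert s["median"] == pytest.approx(np.percentile(v, 50))
    iqr = s["q3"] - s["q1"]
    inside = v[(v >= s["q1"] - 1.5 * iqr) & (v <= s["q3"] + 1.5 * iqr)]
    assert s["whisker_low"] == pytest.approx(inside.min())
    assert s["whisker_high"] == pytest.approx(inside.max())
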
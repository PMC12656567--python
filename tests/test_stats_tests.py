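"""Exact Wilcoxon signed-rank, Shapiro-Wilk, Q-Q points."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from grassunmix.datasets import bin_count_histogram
from grassunmix.errors import DataError, NumericalError
from grassunmix.stats_tests import (
    paired_bin_differences,
    qq_points,
    shapiro_wilk,
    signed_rank_null_distribution,
    wilcoxon_signed_rank_exact,
)


def enumerate_wilcoxon(d):
    """Oracle: V and two-sided p by explicit enumeration of all 2^n signs."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    total = len(vs)
    p_le = sum(v <= v_obs for v in vs) / total
    p_ge = sum(v >= v_obs for v in vs) / total
    return v_obs, min(1.0, 2 * min(p_le, p_ge))


class TestPairedBinDifferences:
    def test_identical_histograms_give_zeros(self):
        h = bin_count_histogram("forbs", 2018)
        assert np.array_equal(paired_bin_differences(h, h), np.zeros(10))

    def test_first_bin_of_packaged_herbaceous_pair(self):
        d = paired_bin_differences(
            bin_count_histogram("herbaceous", 2018),
            bin_count_histogram("herbaceous", 2022),
        )
        assert d[0] == 39728 - 110840 == -71112

    def test_antisymmetry(self):
        a = bin_count_histogram("bare_soil", 2018)
        b = bin_count_histogram("bare_soil", 2022)
        assert np.array_equal(
            paired_bin_differences(a, b), -paired_bin_differences(b, a)
        )

    def test_bin_mismatch_is_error(self):
        import dataclasses

        a = bin_count_histogram("forbs", 2018)
        b = dataclasses.replace(a, counts=a.counts[:5], bin_edges=a.bin_edges[:6])
        with pytest.raises(DataError):
            paired_bin_differences(a, b)


class TestWilcoxonExact:
    def test_three_positive_differences_by_enumeration(self):
        res = wilcoxon_signed_rank_exact([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == 6
        assert res.p_two_sided == pytest.approx(0.25)
        assert res.method == "exact"

    def test_null_distribution_is_normalised(self):
        for n in (1, 5, 10, 20):
            counts = signed_rank_null_distribution(n)
            assert counts.sum() == 2**n
            assert len(counts) == n * (n + 1) // 2 + 1

    def test_convolution_matches_full_enumeration_at_n10(self):
        counts = signed_rank_null_distribution(10)
        brute = np.zeros(56, dtype=int)
        for signs in itertools.product([0, 1], repeat=10):
            brute[sum(r for r, s in zip(range(1, 11), signs) if s)] += 1
        assert np.array_equal(np.array(counts, dtype=int), brute)

    def test_statistic_complementarity(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        vxy = wilcoxon_signed_rank_exact(x, y).statistic
        vyx = wilcoxon_signed_rank_exact(y, x).statistic
        n = np.count_nonzero(x - y)
        assert vxy + vyx == n * (n + 1) / 2

    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_scipy_exact(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-50, 50, size=9).astype(float)
        d = d[d != 0]
        if d.size == 0 or np.unique(np.abs(d)).size < d.size:
            return  # scipy comparison only meaningful tie-free
        res = wilcoxon_signed_rank_exact(d, np.zeros_like(d))
        ref = scipy.stats.wilcoxon(d, alternative="two-sided", method="exact")
        # scipy reports W = min tail sum; ours is the positive-rank sum
        n = d.size
        assert res.statistic in (ref.statistic, n * (n + 1) / 2 - ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank_exact(
            [1.0, 5.0, 5.0, 2.0], [1.0, 4.0, 6.0, 0.0]
        )
        assert res.n_effective == 3
        assert "dropped 1" in res.notes

    def test_all_zero_differences_is_error(self):
        with pytest.raises(DataError):
            wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])

    def test_ties_fall_back_to_normal_approximation(self):
        res = wilcoxon_signed_rank_exact(
            [2.0, 2.0, -2.0, 3.0], [0.0, 0.0, 0.0, 0.0]
        )
        assert res.method == "approximate"
        assert 0 < res.p_two_sided <= 1

    def test_matches_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(10):
            # tie-free |d|: distinct magnitudes with random signs
            mags = rng.choice(np.arange(1, 13), size=8, replace=False)
            d = (mags * rng.choice([-1, 1], size=8)).astype(float)
            res = wilcoxon_signed_rank_exact(d, np.zeros_like(d))
            v, p = enumerate_wilcoxon(d)
            assert res.statistic == v
            assert res.p_two_sided == pytest.approx(p, abs=1e-12)


class TestShapiroWilk:
    def test_symmetric_three_point_sample_is_exactly_normal_scoring(self):
        # closed form at n=3: coefficients (sqrt(1/2), 0, -sqrt(1/2))
        res = shapiro_wilk(np.array([-1.0, 0.0, 1.0]))
        assert res.statistic == pytest.approx(1.0, abs=1e-6)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        w1 = shapiro_wilk(x).statistic
        w2 = shapiro_wilk(3.7 * x + 11.0).statistic
        assert w1 == pytest.approx(w2, abs=1e-10)

    @pytest.mark.parametrize("n", [2, 5001])
    def test_sample_size_limits(self, n):
        with pytest.raises(DataError):
            shapiro_wilk(np.arange(n, dtype=float))

    def test_zero_variance_is_error(self):
        with pytest.raises(NumericalError):
            shapiro_wilk(np.full(10, 3.0))

    def test_w_bounded(self, rng):
        res = shapiro_wilk(rng.exponential(size=50))
        assert 0 < res.statistic <= 1


class TestQQPoints:
    def test_two_point_positions(self):
        pts = qq_points(np.array([5.0, 3.0]))
        expected = scipy.stats.norm.ppf(
            [(1 - 0.375) / 2.25, (2 - 0.375) / 2.25]
        )
        assert np.allclose(pts[:, 0], expected)
        assert np.array_equal(pts[:, 1], [3.0, 5.0])

    def test_monotone_in_both_coordinates(self, rng):
        pts = qq_points(rng.normal(size=40))
        assert np.all(np.diff(pts[:, 0]) > 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_positions_symmetric_about_zero(self):
        pts = qq_points(np.arange(9, dtype=float))
        assert np.allclose(pts[:, 0], -pts[::-1, 0], atol=1e-12)

    def test_single_point_is_error(self):
        with pytest.raises(DataError):
            qq_points(np.array([1.0]))
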
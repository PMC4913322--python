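"""Rank statistics against independent brute-force oracles.

The oracles here enumerate the exact null distributions directly
(all sign assignments, all group splits, all rank permutations) and never
touch the implementation's code paths.
"""

from itertools import combinations, permutations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats as sps

from oncoscape import stats as st

# ---------------------------------------------------------------------------
# oracles


def signed_rank_oracle(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    signs = np.array(list(product([0.0, 1.0], repeat=n)))
    ws = signs @ ranks
    lower = np.mean(ws <= w + 1e-9)
    upper = np.mean(ws >= w - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def rank_sum_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = ranks[: x.size].sum()
    ws = np.array([sum(ranks[list(c)]) for c in combinations(range(pooled.size), x.size)])
    lower = np.mean(ws <= w + 1e-9)
    upper = np.mean(ws >= w - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def spearman_perm_oracle(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    vals = [abs(np.corrcoef(rx, np.array(p))[0, 1]) for p in permutations(ry)]
    return float(np.mean(np.array(vals) >= obs - 1e-12))


def bh_oracle(p):
    """Step-up formula applied literally."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for i_rank, idx in enumerate(order, start=1):
        cands = [
            p[jdx] * m / j_rank
            for j_rank, jdx in enumerate(order, start=1)
            if j_rank >= i_rank
        ]
        q[idx] = min(1.0, min(cands))
    return q


# ---------------------------------------------------------------------------
# signed-rank


class TestSignedRank:
    def test_identical_vectors_degenerate(self):
        r = st.wilcoxon_signed_rank([3.0, 1.0, 2.0], [3.0, 1.0, 2.0])
        assert r.p_two_sided == 1.0
        assert r.direction == 0
        assert r.n_effective == 0

    def test_five_positive_differences(self):
        # P(W >= 15) = 1/32 doubled
        r = st.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], np.zeros(5))
        assert r.p_two_sided == pytest.approx(0.0625)
        assert r.direction == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            st.wilcoxon_signed_rank([1.0, 2.0], [1.0])

    @pytest.mark.parametrize("n", [4, 6, 8, 11])
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(25):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r = st.wilcoxon_signed_rank(x, y)
            assert r.p_two_sided == pytest.approx(signed_rank_oracle(x, y), abs=1e-12)

    def test_matches_oracle_with_ties(self, rng):
        for _ in range(25):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.integers(0, 4, size=8).astype(float)
            r = st.wilcoxon_signed_rank(x, y)
            assert r.p_two_sided == pytest.approx(signed_rank_oracle(x, y), abs=1e-12)

    def test_exact_and_approx_agree_at_crossover(self, rng):
        """At the exact/approximate switch size the two paths give nearly
        identical p-values on random continuous data."""
        n = st.SIGNED_RANK_EXACT_MAX
        worst = 0.0
        for _ in range(1000):
            d = rng.normal(loc=rng.normal(scale=0.5), size=n)
            exact = st.wilcoxon_signed_rank(d).p_two_sided
            # approximation path: tie-corrected normal with continuity corr.
            ranks = sps.rankdata(np.abs(d[d != 0]))
            w = ranks[d[d != 0] > 0].sum()
            m = ranks.size
            mu = m * (m + 1) / 4
            var = m * (m + 1) * (2 * m + 1) / 24
            z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
            approx = min(1.0, 2 * sps.norm.sf(abs(z)))
            worst = max(worst, abs(exact - approx))
        assert worst < 0.02


# ---------------------------------------------------------------------------
# rank-sum


class TestRankSum:
    def test_two_vs_two(self):
        r = st.wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert r.p_two_sided == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        r = st.wilcoxon_rank_sum([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert r.p_two_sided == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("nx,ny", [(2, 3), (5, 5), (4, 8), (6, 6)])
    def test_matches_enumeration_oracle(self, nx, ny, rng):
        for _ in range(25):
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            r = st.wilcoxon_rank_sum(x, y)
            assert r.p_two_sided == pytest.approx(rank_sum_oracle(x, y), abs=1e-12)

    def test_matches_oracle_with_ties(self, rng):
        for _ in range(25):
            x = rng.integers(0, 3, size=5).astype(float)
            y = rng.integers(0, 3, size=6).astype(float)
            r = st.wilcoxon_rank_sum(x, y)
            assert r.p_two_sided == pytest.approx(rank_sum_oracle(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# BH adjustment


class TestBH:
    def test_single_p_identity(self):
        assert st.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_example(self):
        q = st.bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert q == pytest.approx([0.02, 0.04, 0.04, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.bh_adjust([0.5, 1.2])

    def test_nan_passthrough(self):
        q = st.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # the NaN does not count towards m
        assert q[0] == pytest.approx(0.02)

    def test_matches_literal_stepup_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            q = st.bh_adjust(p)
            assert q == pytest.approx(bh_oracle(p), abs=1e-12)
            assert q == pytest.approx(
                multipletests(p, method="fdr_bh")[1], abs=1e-12
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st_h.lists(st_h.floats(0, 1), min_size=1, max_size=40))
    def test_stepup_properties(self, p):
        q = st.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_perfect_antimonotone(self):
        r = st.spearman([1, 2, 3], [3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_hand_worked_rank_pearson(self):
        r = st.spearman([1, 2, 3], [1, 3, 2])
        assert r.rho == pytest.approx(0.5)

    def test_constant_vector_degenerate(self):
        r = st.spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert r.degenerate

    def test_p_matches_permutation_oracle(self, rng):
        for n in (5, 6):
            for _ in range(10):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                r = st.spearman(x, y)
                assert r.p_two_sided == pytest.approx(
                    spearman_perm_oracle(x, y), abs=1e-12
                )

    def test_rho_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            r = st.spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert r.rho == pytest.approx(ref.statistic, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st_h.lists(
            st_h.tuples(
                st_h.floats(-100, 100, allow_nan=False),
                st_h.floats(-100, 100, allow_nan=False),
            ),
            min_size=4,
            max_size=20,
        )
    )
    def test_rank_invariance(self, pairs):
        """spearman(x, y) == spearman(rank(x), rank(y)) exactly."""
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        r1 = st.spearman(x, y)
        r2 = st.spearman(sps.rankdata(x), sps.rankdata(y))
        if r1.degenerate:
            assert r2.degenerate
        else:
            assert r1.rho == pytest.approx(r2.rho, abs=1e-12)
            assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)


# ---------------------------------------------------------------------------
# quantiles


class TestQuantile:
    def test_linear_interpolation(self):
        assert st.quantile(np.arange(1, 101), 0.25) == pytest.approx(25.75)

    def test_boundaries_and_constants(self, rng):
        v = rng.normal(size=17)
        assert st.quantile(v, 0.0) == v.min()
        assert st.quantile(v, 1.0) == v.max()
        assert st.quantile(np.full(9, 3.3), 0.77) == pytest.approx(3.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.quantile([], 0.5)
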
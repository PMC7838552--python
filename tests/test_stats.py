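"""Monte-Carlo rank tests against exhaustive-permutation oracles, the
Kendall W transformation, and the pairwise battery."""

import itertools

import numpy as np
import pytest
from scipy.stats import kruskal, rankdata

from micropursuit import (
    SubjectConditionMatrix,
    friedman_mc,
    kendall_w,
    kruskal_wallis_mc,
    mann_whitney_mc,
    pairwise_battery,
    wilcoxon_signed_rank_mc,
)
from micropursuit.errors import (
    AllZeroDifferencesError,
    BadArgsError,
    EmptyGroupError,
    IncompleteMatrixError,
)
from micropursuit.stats import _friedman_chi2_from_ranks


def mc_tol(p, n_perm):
    """Three Monte-Carlo standard errors around an exact p."""
    return 3 * np.sqrt(p * (1 - p) / n_perm)


class TestFriedman:
    def test_perfect_concordance_statistic(self):
        """Fully concordant N=3, k=3 rankings give chi2 = N(k-1) = 6."""
        m = SubjectConditionMatrix(np.array([[1.0, 2, 3]] * 3), ("a", "b", "c"))
        res = friedman_mc(m, n_perm=200, seed=0)
        assert res.statistic == pytest.approx(6.0)
        assert res.effect_size_w == pytest.approx(1.0)

    def test_identical_conditions_null(self):
        m = SubjectConditionMatrix(np.ones((5, 3)), ("a", "b", "c"))
        res = friedman_mc(m, n_perm=500, seed=0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_mc == 1.0

    def test_against_exhaustive_enumeration(self):
        """N=4, k=2: p from all 2^4 within-subject label swaps."""
        rng = np.random.default_rng(5)
        values = rng.normal(size=(4, 2))
        values[:, 1] += 1.0
        ranks = rankdata(values, axis=1)
        obs = _friedman_chi2_from_ranks(ranks)
        null = []
        for flips in itertools.product([0, 1], repeat=4):
            perm = np.array(
                [row[::-1] if f else row for row, f in zip(ranks, flips)]
            )
            null.append(_friedman_chi2_from_ranks(perm))
        p_exact = np.mean(np.array(null) >= obs - 1e-12)
        m = SubjectConditionMatrix(values, ("a", "b"))
        res = friedman_mc(m, n_perm=10_000, seed=1)
        assert res.statistic == pytest.approx(obs)
        assert abs(res.p_mc - p_exact) < mc_tol(p_exact, 10_000) + 1e-4

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(IncompleteMatrixError):
            SubjectConditionMatrix(np.array([[1.0, np.nan]]), ("a", "b"))


class TestKendallW:
    @pytest.mark.parametrize(
        "chi2,n,k,expected,places",
        [
            (23.565, 23, 3, 0.512, 3),
            (37.130, 23, 3, 0.807, 3),
            (23.0, 23, 2, 1.0, 3),
            (8.667, 9, 3, 0.481, 3),
            (9.0, 9, 2, 1.0, 3),
            (8.6, 10, 3, 0.43, 2),
            (2.4, 10, 3, 0.12, 2),
            (1.6, 10, 2, 0.16, 2),
        ],
    )
    def test_published_worked_examples(self, chi2, n, k, expected, places):
        """W = chi2 / (N(k-1)) reproduces the reported effect sizes."""
        assert round(kendall_w(chi2, n, k), places) == pytest.approx(expected)

    def test_perfect_concordance_is_one_for_all_shapes(self):
        for n in (2, 5, 23):
            for k in (2, 3, 5):
                assert kendall_w(n * (k - 1), n, k) == 1.0

    def test_bad_args(self):
        with pytest.raises(BadArgsError):
            kendall_w(-1.0, 5, 3)
        with pytest.raises(BadArgsError):
            kendall_w(1.0, 5, 1)


class TestWilcoxon:
    def test_exhaustive_oracle_n5(self):
        """p matches full enumeration of the 2^5 sign patterns."""
        rng = np.random.default_rng(2)
        d = rng.normal(0.8, 1.0, 5)
        r = rankdata(np.abs(d))
        denom = np.sqrt((r**2).sum())
        obs = abs((np.sign(d) * r).sum() / denom)
        null = [
            abs((np.array(signs) * r).sum() / denom)
            for signs in itertools.product([-1, 1], repeat=5)
        ]
        p_exact = np.mean(np.array(null) >= obs - 1e-12)
        res = wilcoxon_signed_rank_mc(d, n_perm=10_000, seed=3)
        assert abs(res.p_mc - p_exact) < mc_tol(p_exact, 10_000) + 1e-4

    def test_sign_convention(self):
        a = np.array([2.0, 3.0, 4.0, 5.0])
        b = a - 1.0
        res = wilcoxon_signed_rank_mc(a, b, n_perm=100, seed=0)
        assert res.statistic > 0  # condition1 - condition2 positive

    def test_all_zero_differences(self):
        with pytest.raises(AllZeroDifferencesError):
            wilcoxon_signed_rank_mc(np.ones(5), np.ones(5), n_perm=10, seed=0)


class TestKruskalWallisAndMWW:
    def test_kw_statistic_matches_scipy(self, rng):
        groups = [rng.normal(s * 0.5, 1, 12) for s in range(3)]
        res = kruskal_wallis_mc(groups, n_perm=100, seed=0)
        assert res.statistic == pytest.approx(kruskal(*groups).statistic)

    def test_kw_exhaustive_oracle_tiny(self):
        """3+3 observations: p from all C(6,3) label splits."""
        x = np.array([0.1, 0.5, 0.9])
        y = np.array([1.2, 1.7, 2.5])
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)

        def h_stat(idx):
            r1 = ranks[list(idx)]
            rest = [i for i in range(6) if i not in idx]
            r2 = ranks[rest]
            n = 6
            return (
                12 / (n * (n + 1)) * (r1.sum() ** 2 / 3 + r2.sum() ** 2 / 3)
                - 3 * (n + 1)
            )

        obs = h_stat((0, 1, 2))
        null = [h_stat(c) for c in itertools.combinations(range(6), 3)]
        p_exact = np.mean(np.array(null) >= obs - 1e-12)
        res = kruskal_wallis_mc([x, y], n_perm=10_000, seed=4)
        assert abs(res.p_mc - p_exact) < mc_tol(p_exact, 10_000) + 1e-4

    def test_mww_exhaustive_oracle_tiny(self):
        x = np.array([0.3, 1.1, 2.0])
        y = np.array([1.5, 2.2, 3.3])
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        mu, sd = 3 * 7 / 2, np.sqrt(3 * 3 * 7 / 12)
        obs = abs((ranks[:3].sum() - mu) / sd)
        null = [
            abs((ranks[list(c)].sum() - mu) / sd)
            for c in itertools.combinations(range(6), 3)
        ]
        p_exact = np.mean(np.array(null) >= obs - 1e-12)
        res = mann_whitney_mc(x, y, n_perm=10_000, seed=4)
        assert abs(res.p_mc - p_exact) < mc_tol(p_exact, 10_000) + 1e-4

    def test_identical_groups_null(self, rng):
        g = rng.normal(size=30)
        res = kruskal_wallis_mc([g, g], n_perm=1000, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_mc > 0.9

    def test_large_shift_power(self, rng):
        g1 = rng.normal(0, 1, 50)
        g2 = rng.normal(2, 1, 50)
        res = mann_whitney_mc(g1, g2, n_perm=10_000, seed=0)
        assert res.p_mc < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroupError):
            kruskal_wallis_mc([np.array([1.0]), np.array([])], n_perm=10)

    def test_monotone_transform_invariance(self, rng):
        """Rank tests are invariant to monotone transforms at matched seeds."""
        g1, g2 = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        r1 = mann_whitney_mc(g1, g2, n_perm=2000, seed=9)
        r2 = mann_whitney_mc(np.exp(g1), np.exp(g2), n_perm=2000, seed=9)
        assert r1.p_mc == r2.p_mc and r1.statistic == pytest.approx(r2.statistic)


class TestPairwiseBattery:
    def test_three_conditions_three_pairs(self, rng):
        m = SubjectConditionMatrix(rng.normal(size=(8, 3)), ("FX", "RW", "LJ"))
        results = pairwise_battery(m, n_perm=500, seed=0)
        assert len(results) == 3
        assert results[0].extra["alpha"] == pytest.approx(0.05 / 3)

    def test_two_conditions_plain_alpha(self, rng):
        m = SubjectConditionMatrix(rng.normal(size=(8, 2)), ("RW", "LJ"))
        results = pairwise_battery(m, n_perm=500, seed=0)
        assert len(results) == 1
        assert results[0].extra["alpha"] == pytest.approx(0.05)

    def test_null_data_rarely_flagged(self, rng):
        flags = 0
        for _ in range(20):
            m = SubjectConditionMatrix(rng.normal(size=(10, 3)),
                                       ("a", "b", "c"))
            flags += sum(r.extra["flagged"]
                         for r in pairwise_battery(m, n_perm=400, seed=1))
        assert flags <= 4  # 60 null tests at criterion 0.0167


class TestTypeIError:
    """Each MC test keeps its size at alpha = 0.05 under its null
    (binomial 95% band for 1000 replicates: [0.036, 0.064])."""

    N_REP = 1000
    N_PERM = 499

    def _band(self, rejections):
        rate = rejections / self.N_REP
        assert 0.036 <= rate <= 0.064, f"type-I rate {rate:.3f}"

    def test_friedman(self):
        rng = np.random.default_rng(101)
        rej = 0
        for i in range(self.N_REP):
            m = SubjectConditionMatrix(rng.normal(size=(20, 3)),
                                       ("a", "b", "c"))
            rej += friedman_mc(m, n_perm=self.N_PERM,
                               seed=int(rng.integers(2**31))).p_mc < 0.05
        self._band(rej)

    def test_wilcoxon(self):
        rng = np.random.default_rng(102)
        rej = 0
        for i in range(self.N_REP):
            d = rng.normal(0, 1, 20)
            rej += wilcoxon_signed_rank_mc(
                d, n_perm=self.N_PERM, seed=int(rng.integers(2**31))
            ).p_mc < 0.05
        self._band(rej)

    def test_kruskal_wallis(self):
        rng = np.random.default_rng(103)
        rej = 0
        for i in range(self.N_REP):
            groups = [rng.normal(0, 1, 15) for _ in range(3)]
            rej += kruskal_wallis_mc(
                groups, n_perm=self.N_PERM, seed=int(rng.integers(2**31))
            ).p_mc < 0.05
        self._band(rej)

    def test_mann_whitney(self):
        rng = np.random.default_rng(104)
        rej = 0
        for i in range(self.N_REP):
            rej += mann_whitney_mc(
                rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                n_perm=self.N_PERM, seed=int(rng.integers(2**31)),
            ).p_mc < 0.05
        self._band(rej)
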
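"""Effect sizes, BH-FDR, permutation tests, and two-sample t-tests."""

import numpy as np
import pytest
from scipy import stats

from hubdegree import (
    bh_fdr,
    cohens_d,
    correlation_permutation_test,
    group_permutation_test,
    ttest_from_stats,
    ttest_two_sample,
)


class TestCohensD:
    def test_identical_groups_give_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_shift_unit_sd(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(2000)
        base = (base - base.mean()) / base.std(ddof=1)
        assert cohens_d(base + 1, base) == pytest.approx(1.0)

    def test_hand_computed_pooled_sd(self):
        assert cohens_d([2, 4], [1, 3]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError):
            cohens_d([1, 1], [2, 2])


class TestBHFDR:
    def brute_force(self, p, alpha):
        """Step-up: largest k with p_(k) <= k*alpha/m; reject the k smallest."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        reject = np.zeros(m, dtype=bool)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * alpha / m:
                k_star = k
        reject[order[:k_star]] = True
        return reject

    def test_step_up_rejects_all_four(self):
        q, rej = bh_fdr([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert rej.all()

    def test_all_ones_rejects_none(self):
        q, rej = bh_fdr(np.ones(5), alpha=0.05)
        assert not rej.any()
        np.testing.assert_allclose(q, 1.0)

    def test_single_p(self):
        q, rej = bh_fdr([0.04], alpha=0.05)
        assert rej[0] and q[0] == pytest.approx(0.04)

    def test_empty_input(self):
        q, rej = bh_fdr([], alpha=0.05)
        assert q.size == 0 and rej.size == 0

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            m = rng.integers(1, 7)
            p = rng.random(m).round(2)
            alpha = rng.choice([0.01, 0.05, 0.1, 0.25])
            _, rej = bh_fdr(p, alpha=alpha)
            np.testing.assert_array_equal(rej, self.brute_force(p, alpha))


class TestGroupPermutationTest:
    def test_zero_observed_difference_gives_p_one(self):
        # each group holds the same multiset of values, so the diff is 0
        X = np.repeat(np.arange(3.0), 2)[:, None] * np.ones((1, 3))
        labels = ["a", "b"] * 3
        res = group_permutation_test(X, labels, n_perm=200, seed=0)
        np.testing.assert_allclose(res["statistic"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 20))
        X[:20, 3] += 2.5
        labels = ["a"] * 20 + ["b"] * 20
        res = group_permutation_test(X, labels, n_perm=1000, seed=2)
        assert res["significant"].iloc[3]
        assert res["d"].iloc[3] > 1.5
        # the null parcels stay mostly non-significant
        assert res["significant"].drop(res.index[3]).sum() <= 1

    def test_z_and_p_orderings_agree(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 40)) + rng.normal(0, 0.5, size=40)
        labels = ["a"] * 15 + ["b"] * 15
        res = group_permutation_test(X, labels, n_perm=2000, seed=3)
        rho = stats.spearmanr(np.abs(res["z"]), -res["p"]).statistic
        assert rho > 0.95

    def test_doubling_permutations_within_mc_error(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 5))
        labels = ["a"] * 15 + ["b"] * 15
        r1 = group_permutation_test(X, labels, n_perm=2000, seed=1)
        r2 = group_permutation_test(X, labels, n_perm=4000, seed=7)
        mc_sd = np.sqrt(r1["p"] * (1 - r1["p"]) / 2000).to_numpy()
        assert np.all(np.abs(r1["p"].to_numpy() - r2["p"].to_numpy())
                      <= 4 * mc_sd + 2 / 2000)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_permutation_test(np.zeros((4, 2)), ["a"] * 4, n_perm=100)

    def test_add_one_correction_avoids_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2))
        X[:10] += 50
        labels = ["a"] * 10 + ["b"] * 10
        res = group_permutation_test(X, labels, n_perm=200, seed=0, add_one=True)
        assert np.all(res["p"] > 0)


class TestCorrelationPermutationTest:
    def test_perfect_correlation_detected(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 10))
        y = X[:, 4].copy()
        res = correlation_permutation_test(X, y, n_perm=500, seed=1)
        assert res["r"].iloc[4] == pytest.approx(1.0)
        assert res["p"].iloc[4] < 1e-6
        assert res["significant"].iloc[4]

    def test_exactly_orthogonal_behavior_gives_z_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(24)
        y = rng.standard_normal(24)
        y -= y.mean()
        xc = x - x.mean()
        y -= xc * (xc @ y) / (xc @ xc)  # r(x, y) = 0 exactly
        res = correlation_permutation_test(x[:, None], y, n_perm=300, seed=3)
        assert res["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["z"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["p"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_behavior_rejected(self):
        with pytest.raises(ValueError):
            correlation_permutation_test(np.ones((6, 2)), np.ones(6), n_perm=100)

    def test_family_threshold_applied(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        res = correlation_permutation_test(
            X, y, n_perm=500, seed=5, family_alpha=0.025
        )
        assert res["significant"].equals(res["q"] < 0.025)


class TestTwoSampleTTest:
    # summary statistics from the study's demographics/performance table
    @pytest.mark.parametrize(
        "a, b, expected_p",
        [
            ((84.5, 10.1, 29), (91.5, 6.0, 29), 0.002),   # WM accuracy (%)
            ((949.6, 147.7, 29), (879.5, 129.7, 29), 0.059),  # WM RT (ms)
            ((100.2, 11.8, 27), (109.3, 10.2, 29), 0.003),  # verbal IQ
        ],
    )
    def test_reproduces_printed_p_values(self, a, b, expected_p):
        res = ttest_from_stats(*a, *b, variant="pooled")
        assert res.p == pytest.approx(expected_p, abs=1e-3)

    def test_identical_summaries(self):
        res = ttest_from_stats(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_raw_samples_match_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(12) + 0.5, rng.standard_normal(15)
        ours = ttest_two_sample(a, b)
        ref = stats.ttest_ind(a, b)
        assert ours.t == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_welch_variant(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal(12) * 3, rng.standard_normal(30)
        ours = ttest_two_sample(a, b, variant="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert ours.t == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ttest_from_stats(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            ttest_from_stats(1, 1.0, 1, 2, 1.0, 10)
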
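"""Wilcoxon signed-rank test, effect sizes, and correlation inference."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from sjtbw import (
    GroupSummary,
    PairedSummary,
    cohens_d_pooled,
    cohens_dz,
    correlation_strength,
    effect_size_r,
    no_correlation_test,
    spearman_rho,
    wilcoxon_signed_rank,
)


def brute_force_signflip_p(diffs):
    """Exact two-sided p by explicit enumeration of every sign assignment."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    sums = []
    for signs in itertools.product((0, 1), repeat=n):
        sums.append(np.dot(signs, ranks))
    sums = np.asarray(sums)
    lower = np.mean(sums <= w_obs + 1e-9)
    upper = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


class TestWilcoxon:
    def test_all_positive_ranks_closed_form(self):
        """Differences with ranks 1..10 all positive: W = 55 and
        z = 27.5 / sqrt(96.25)."""
        x1 = np.arange(1.0, 11.0)
        res = wilcoxon_signed_rank(x1, np.zeros(10))
        assert res.W == 55.0
        assert res.z == pytest.approx(27.5 / math.sqrt(96.25), abs=1e-12)
        assert res.z == pytest.approx(2.803, abs=5e-4)

    def test_antisymmetric_differences_give_zero_z(self):
        d = np.array([3.0, -3.0, 1.0, -1.0, 2.0, -2.0])
        res = wilcoxon_signed_rank(d, np.zeros(6))
        assert res.z == 0.0
        assert res.p_two_sided == 1.0

    def test_zero_differences_dropped(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        x2 = x1.copy()
        x2[:5] -= np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        res = wilcoxon_signed_rank(x1, x2)
        assert res.n_nonzero == 5

    def test_degenerate_all_zero(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(0.3, 1, 12)
        x2 = rng.normal(0.0, 1, 12)
        res = wilcoxon_signed_rank(x1, x2)
        ref = stats.wilcoxon(x1, x2, correction=False, method="approx")
        assert abs(res.z) == pytest.approx(abs(ref.zstatistic), abs=1e-10)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_p_equals_brute_force(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.4, 1.0, 8)
        res = wilcoxon_signed_rank(d, np.zeros(8))
        assert res.p_exact == pytest.approx(brute_force_signflip_p(d),
                                            abs=1e-12)

    def test_normal_approx_close_to_exact_in_decision_region_n8(self):
        """At n = 8, for outcomes with exact p in the decision region the
        z-based p agrees with the 2^8 enumeration within 0.03."""
        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(40):
            d = rng.normal(0.9, 1.0, 8)
            res = wilcoxon_signed_rank(d, np.zeros(8))
            p_bf = brute_force_signflip_p(d)
            assert res.p_exact == pytest.approx(p_bf, abs=1e-12)
            if p_bf <= 0.1:
                assert abs(res.p_two_sided - p_bf) < 0.03
                checked += 1
        assert checked >= 10  # the fixture actually exercises the region

    @given(st.integers(min_value=0, max_value=200),
           st.integers(min_value=5, max_value=15))
    def test_approx_vs_exact_property(self, seed, n):
        """Normal-approximation p stays within 0.03 of the exact sign-flip
        p whenever the exact p is decision-relevant (<= 0.1); near the
        center of the coarse discrete null the conventions diverge more."""
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, n)
        res = wilcoxon_signed_rank(d, np.zeros(n))
        assert res.p_exact is not None
        if res.p_exact <= 0.1:
            assert abs(res.p_two_sided - res.p_exact) < 0.03

    def test_tied_absolute_differences_average_ranked(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 3.0])
        res = wilcoxon_signed_rank(d, np.zeros(5))
        # |d| ranks: three 1.0s share (1+2+3)/3 = 2, then 4, 5
        assert res.W == 2.0 + 2.0 + 4.0 + 5.0


class TestEffectSizes:
    @pytest.mark.parametrize("z,n,expected", [
        (2.29, 20, 0.51),
        (2.52, 20, 0.56),
        (0.0, 20, 0.0),
    ])
    def test_r_from_z(self, z, n, expected):
        assert round(effect_size_r(z, n), 2) == expected

    def test_r_symmetric_in_sign(self):
        assert effect_size_r(-2.29, 20) == effect_size_r(2.29, 20)

    @pytest.mark.parametrize("m1,m2,s1,s2,rho,expected", [
        (2.92, 0.98, 1.97, 1.10, 0.44, 1.09),  # congruency with saltiness
        (5.52, 2.96, 0.67, 1.69, 0.54, 1.77),  # edibility
        (4.48, 3.35, 1.26, 1.13, 0.10, 0.70),  # familiarity
        (3.01, 3.00, 1.00, 1.18, -0.43, 0.01),  # liking
    ])
    def test_dz_reproduces_reported_values(self, m1, m2, s1, s2, rho, expected):
        s = PairedSummary(mean_1=m1, mean_2=m2, sd_1=s1, sd_2=s2, rho=rho,
                          n_pairs=10)
        assert round(cohens_dz(s), 2) == expected

    def test_dz_zero_when_means_equal(self):
        s = PairedSummary(mean_1=1.0, mean_2=1.0, sd_1=0.5, sd_2=0.7,
                          rho=0.3, n_pairs=10)
        assert cohens_dz(s) == 0.0

    def test_dz_uncorrelated_reduction(self):
        """rho = 0 reduces to |dm| / sqrt(s1^2 + s2^2)."""
        s = PairedSummary(mean_1=2.0, mean_2=1.0, sd_1=0.6, sd_2=0.8,
                          rho=0.0, n_pairs=10)
        assert cohens_dz(s) == pytest.approx(1.0 / math.sqrt(1.0))

    def test_dz_equal_sds_reduction(self):
        """Equal SDs: d_z = |dm| / (s sqrt(2 - 2 rho))."""
        s = PairedSummary(mean_1=2.0, mean_2=1.0, sd_1=0.5, sd_2=0.5,
                          rho=0.6, n_pairs=10)
        assert cohens_dz(s) == pytest.approx(
            1.0 / (0.5 * math.sqrt(2 - 1.2)))

    def test_dz_degenerate_denominator(self):
        s = PairedSummary(mean_1=2.0, mean_2=1.0, sd_1=0.5, sd_2=0.5,
                          rho=1.0, n_pairs=10)
        with pytest.raises(ValueError):
            cohens_dz(s)

    def test_pooled_d_reported_value(self):
        """Group summaries (0.29, 0.08) vs (0.39, 0.11) at equal n -> 1.04."""
        g1 = GroupSummary(mean=0.29, sd=0.08, n=10)
        g2 = GroupSummary(mean=0.39, sd=0.11, n=10)
        assert round(cohens_d_pooled(g1, g2), 2) == 1.04

    def test_pooled_d_hand_arithmetic_unequal_n(self):
        g1 = GroupSummary(mean=0.0, sd=1.0, n=4)
        g2 = GroupSummary(mean=1.0, sd=2.0, n=12)
        assert cohens_d_pooled(g1, g2) == pytest.approx(
            1.0 / math.sqrt((4 + 48) / 16), rel=1e-12)

    def test_pooled_d_symmetric_and_zero_cases(self):
        g1 = GroupSummary(mean=0.3, sd=0.1, n=8)
        g2 = GroupSummary(mean=0.5, sd=0.2, n=8)
        assert cohens_d_pooled(g1, g2) == cohens_d_pooled(g2, g1)
        assert cohens_d_pooled(g1, g1) == 0.0


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        y = x**3 + 2
        assert spearman_rho(x, y) == pytest.approx(1.0)
        assert spearman_rho(x[::-1], y) == pytest.approx(-1.0)

    def test_tied_heavy_fixture_matches_rank_pearson(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([2.0, 3.0, 3.0, 3.0, 5.0, 5.0, 6.0, 6.0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)
        ref, _ = stats.spearmanr(x, y)
        assert spearman_rho(x, y) == pytest.approx(ref, abs=1e-12)

    def test_zero_rank_variance_is_nan(self):
        assert math.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestNoCorrelationTest:
    def test_reported_t_value(self):
        """rho = 0.52, n = 20 -> t(18) = 2.58."""
        res = no_correlation_test(0.52, 20)
        assert res.df == 18
        assert round(res.t, 2) == 2.58
        assert res.p_two_sided < 0.05

    def test_null_rho(self):
        res = no_correlation_test(0.0, 20)
        assert res.t == 0.0
        assert res.p_two_sided == 1.0
        assert res.strength_label == "none"

    @pytest.mark.parametrize("rho,label", [
        (0.0, "none"), (0.2, "weak"), (-0.39, "weak"), (0.4, "moderate"),
        (0.48, "moderate"), (-0.69, "moderate"), (0.71, "strong"),
        (-0.99, "strong"), (1.0, "perfect"),
    ])
    def test_strength_labels(self, rho, label):
        assert correlation_strength(rho) == label

    def test_p_monotone_in_abs_rho(self):
        rhos = np.linspace(0.0, 0.95, 20)
        ps = [no_correlation_test(r, 20).p_two_sided for r in rhos]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            no_correlation_test(1.0, 20)
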
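"""Self-implemented tests/intervals against enumeration and identity oracles."""

import math
from itertools import permutations

import numpy as np
import pytest
from scipy import optimize, stats

from ssapkit.inference import (chisq_ratio_gof, fisher_exact_one_sided,
                               holm_adjust, mantel_test, newcombe_wilson_ci,
                               oneway_anova_tukey, yates_chisq_2x2)


def random_2x2(rng, max_count=40):
    while True:
        t = rng.integers(0, max_count, size=(2, 2))
        if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
            return t


class TestYates2x2:
    def test_no_association(self):
        res = yates_chisq_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_one_sided == pytest.approx(0.5)

    def test_shortcut_formula(self):
        """Matches the closed-form N(|ad-bc|-N/2)^2 / (r1 r2 c1 c2)."""
        a, b, c, d = 18, 48, 38, 28
        n = a + b + c + d
        shortcut = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        res = yates_chisq_2x2([[a, b], [c, d]])
        assert res.statistic == pytest.approx(shortcut, rel=1e-12)
        assert res.statistic == pytest.approx(11.20, abs=0.005)

    def test_correction_never_exceeds_uncorrected(self, rng):
        for _ in range(200):
            t = random_2x2(rng)
            corrected = yates_chisq_2x2(t).statistic
            uncorrected = stats.chi2_contingency(t, correction=False)[0]
            assert corrected <= uncorrected + 1e-12

    def test_direction_gated_one_sided_p(self):
        t = [[30, 10], [10, 30]]
        res = yates_chisq_2x2(t)
        assert res.direction == "greater"
        with_match = yates_chisq_2x2(t, one_sided_direction="greater")
        against = yates_chisq_2x2(t, one_sided_direction="less")
        assert with_match.p_one_sided == pytest.approx(res.p_two_sided / 2)
        assert against.p_one_sided == pytest.approx(1 - res.p_two_sided / 2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            yates_chisq_2x2([[0, 0], [5, 5]])


class TestRatioGof:
    def test_exact_fit(self):
        assert chisq_ratio_gof((10, 10)).statistic == 0.0

    def test_hand_computed_statistic(self):
        # (30,10) vs 1:1 -> corrected deviation 9.5 on expected 20, both cells
        res = chisq_ratio_gof((30, 10))
        assert res.statistic == pytest.approx(2 * 9.5 ** 2 / 20)
        assert res.statistic == pytest.approx(9.025)

    def test_p_matches_chi2_survival(self, rng):
        for _ in range(100):
            k1, k2 = int(rng.integers(0, 50)), int(rng.integers(1, 50))
            res = chisq_ratio_gof((k1, k2))
            assert res.p_two_sided == pytest.approx(
                stats.chi2.sf(res.statistic, 1))

    def test_non_unit_ratio(self):
        res = chisq_ratio_gof((30, 10), ratio=(3, 1))
        assert res.statistic == 0.0


class TestFisherExact:
    def test_two_equiprobable_tables(self):
        res = fisher_exact_one_sided([[1, 0], [0, 1]])
        assert res.p_one_sided == pytest.approx(0.5)

    def test_identical_rows_no_signal(self):
        res = fisher_exact_one_sided([[5, 5], [5, 5]])
        assert res.p_one_sided > 0.5
        assert res.p_two_sided == pytest.approx(1.0)

    def test_full_enumeration_small_tables(self):
        """One-sided p equals explicit hypergeometric enumeration, N <= 12."""
        def enum_p(a, b, c, d):
            n, r1, c1 = a + b + c + d, a + b, a + c
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            def prob(x):
                return (math.comb(c1, x) * math.comb(n - c1, r1 - x)
                        / math.comb(n, r1))
            mean = r1 * c1 / n
            xs = range(a, hi + 1) if a >= mean else range(lo, a + 1)
            return sum(prob(x) for x in xs)

        count = 0
        for a in range(5):
            for b in range(4):
                for c in range(4):
                    for d in range(4):
                        if a + b + c + d == 0 or a + b + c + d > 12:
                            continue
                        res = fisher_exact_one_sided([[a, b], [c, d]])
                        assert res.p_one_sided == pytest.approx(
                            enum_p(a, b, c, d), abs=1e-12), (a, b, c, d)
                        count += 1
        assert count > 100

    def test_two_sided_matches_scipy(self, rng):
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            ours = fisher_exact_one_sided(t)
            _, p_scipy = stats.fisher_exact(t, alternative="two-sided")
            assert ours.p_two_sided == pytest.approx(p_scipy, abs=1e-9)


class TestWilsonInterval:
    def test_boundaries(self):
        lo, _ = newcombe_wilson_ci(0, 10)
        _, hi = newcombe_wilson_ci(10, 10)
        assert lo == 0.0 and hi == 1.0

    def test_contains_point_estimate(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            lo, hi = newcombe_wilson_ci(k, n)
            assert lo - 1e-12 <= k / n <= hi + 1e-12

    def test_limits_satisfy_score_equation(self, rng):
        """Both endpoints are roots of (p_hat - p)^2 = z^2 p(1-p)/n."""
        z = stats.norm.ppf(0.975)
        for k, n in [(3, 17), (1, 50), (25, 40), (9, 9)]:
            p_hat = k / n
            lo, hi = newcombe_wilson_ci(k, n)
            def score(p):
                return (p_hat - p) ** 2 - z ** 2 * p * (1 - p) / n
            for root in (lo, hi):
                if 0 < root < 1:
                    refined = optimize.brentq(score, max(0, root - 0.05),
                                              min(1, root + 0.05))
                    assert root == pytest.approx(refined, abs=1e-9)


class TestHolm:
    def test_single_p_unchanged(self):
        reject, adj = holm_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert reject[0]

    def test_all_ones_no_rejection(self):
        reject, adj = holm_adjust([1.0, 1.0, 1.0])
        assert not reject.any()
        assert (adj == 1.0).all()

    def test_adjusted_p_monotone_in_sorted_order(self, rng):
        p = rng.random(20)
        _, adj = holm_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_dominates_plain_bonferroni(self, rng):
        """Holm rejects a superset of Bonferroni's rejections."""
        for _ in range(500):
            m = int(rng.integers(1, 12))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            reject, _ = holm_adjust(p, alpha=0.05)
            bonf = p <= 0.05 / m
            assert (reject | ~bonf).all()


class TestAnovaTukey:
    def test_null_data(self):
        table, _ = oneway_anova_tukey([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert table.ss_between == 0.0 and table.f == 0.0

    def test_two_group_f_equals_t_squared(self, rng):
        for _ in range(20):
            g1 = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            g2 = rng.normal(0.5, 1, size=int(rng.integers(3, 12)))
            table, _ = oneway_anova_tukey([g1, g2])
            t_stat, _ = stats.ttest_ind(g1, g2, equal_var=True)
            assert table.f == pytest.approx(t_stat ** 2, rel=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i * 0.3, 1, size=8) for i in range(5)]
        table, _ = oneway_anova_tukey(groups)
        f_ref, p_ref = stats.f_oneway(*groups)
        assert table.f == pytest.approx(f_ref, rel=1e-10)
        assert table.p == pytest.approx(p_ref, rel=1e-10)

    def test_scale_and_shift_invariance(self, rng):
        """Proportions and percentages give identical F statistics."""
        groups = [rng.random(7) for _ in range(7)]
        f1 = oneway_anova_tukey(groups)[0].f
        f2 = oneway_anova_tukey([100 * g for g in groups])[0].f
        f3 = oneway_anova_tukey([g + 5.0 for g in groups])[0].f
        assert f1 == pytest.approx(f2, rel=1e-10)
        assert f1 == pytest.approx(f3, rel=1e-10)

    def test_ss_decomposition_and_df(self, rng):
        groups = [rng.normal(0, 1, size=6) for _ in range(4)]
        table, _ = oneway_anova_tukey(groups)
        allv = np.concatenate(groups)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        assert table.ss_between + table.ss_within == pytest.approx(ss_total)
        assert table.df_between + table.df_within == allv.size - 1

    def test_tukey_matches_scipy_reference(self, rng):
        groups = [rng.normal(i * 0.8, 1, size=6) for i in range(3)]
        _, comps = oneway_anova_tukey(groups)
        ref = stats.tukey_hsd(*groups)
        for comp in comps:
            assert comp.p == pytest.approx(
                ref.pvalue[comp.group_i, comp.group_j], abs=1e-8)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_tukey([[1.0], [2.0, 3.0]])


class TestMantel:
    def _random_dist(self, rng, n):
        x = rng.random((n, 3))
        d = np.array([[np.abs(a - b).sum() for b in x] for a in x])
        return d

    def test_self_correlation(self, rng):
        d = self._random_dist(rng, 6)
        res = mantel_test(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_r_bounded(self, rng):
        for _ in range(10):
            d1 = self._random_dist(rng, 5)
            d2 = self._random_dist(rng, 5)
            res = mantel_test(d1, d2, n_perm=49, seed=1)
            assert -1 <= res.statistic <= 1

    def test_exact_enumeration_four_taxa(self, rng):
        """Permutation p equals exhaustive enumeration over all 4! relabelings."""
        d1 = self._random_dist(rng, 4)
        d2 = self._random_dist(rng, 4)
        res = mantel_test(d1, d2, n_perm=5000, seed=0)  # 4! = 24 -> exhaustive

        def tri(d):
            i, j = np.tril_indices(4, k=-1)
            return d[i, j]

        x = tri(d1)
        obs = np.corrcoef(x, tri(d2))[0, 1]
        rs = []
        for perm in permutations(range(4)):
            p = np.array(perm)
            rs.append(np.corrcoef(x, tri(d2[np.ix_(p, p)]))[0, 1])
        rs = np.array(rs)
        assert res.p_one_sided == pytest.approx((rs >= obs - 1e-12).mean())

    def test_p_floor_with_identity_included(self, rng):
        d1 = self._random_dist(rng, 10)
        res = mantel_test(d1, d1, n_perm=99, seed=3)
        assert res.p_one_sided >= 1 / 100

    def test_label_mismatch_rejected(self, rng):
        d = self._random_dist(rng, 4)
        with pytest.raises(ValueError):
            mantel_test(d, d[:3, :3])
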
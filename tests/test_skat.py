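"""SKAT machinery: null model, quadratic-form statistic, mixture tail
probability and exact single-variant resampling."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from rarecollapse import skat as sk
from rarecollapse.classify import GeneVariantSet
from rarecollapse.io_cohort import CohortGenotypes, SampleManifest, VariantKey

from conftest import make_manifest


class TestFitNull:
    def test_reference_cohort_fitted_probability(self, cohort_manifest):
        null = sk.fit_null(cohort_manifest)
        assert null.mu == pytest.approx(146 / 1541)
        assert null.residuals.sum() == pytest.approx(0.0, abs=1e-9)
        assert 0 < null.mu < 1

    def test_balanced_cohort_residuals(self):
        null = sk.fit_null(make_manifest(50, 50))
        assert set(np.round(null.residuals, 12)) == {0.5, -0.5}

    def test_single_class_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_manifest(5, 0)


class TestSkatStatistic:
    def test_zero_residuals_give_zero(self):
        null = sk.SkatNullModel(y=np.full(10, 0.3), mu=0.3)
        G = np.random.default_rng(0).integers(0, 3, size=(10, 3)).astype(float)
        assert sk.skat_statistic(null, G, np.ones(3)) == 0.0

    def test_single_variant_unit_weight_is_squared_score(self):
        null = sk.fit_null(make_manifest(3, 5))
        g = np.array([1, 0, 2, 0, 0, 1, 0, 0], dtype=float)
        expected = float(null.residuals @ g) ** 2
        assert sk.skat_statistic(null, g[:, None], np.ones(1)) == pytest.approx(expected)

    def test_matches_dense_kernel_oracle(self):
        """Q equals r' K r computed through the explicit n x n kernel
        K = G W^2 G' (an independent evaluation route)."""
        rng = np.random.default_rng(42)
        null = sk.fit_null(make_manifest(12, 18))
        G = rng.integers(0, 3, size=(30, 4)).astype(float)
        w = rng.uniform(0.5, 3.0, size=4)
        K = G @ np.diag(w**2) @ G.T
        expected = float(null.residuals @ K @ null.residuals)
        assert sk.skat_statistic(null, G, w) == pytest.approx(expected, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        n = 40
        y = np.array([1] * 10 + [0] * 30, dtype=float)
        G = rng.integers(0, 3, size=(n, 5)).astype(float)
        w = rng.uniform(0.1, 2.0, size=5)
        perm = rng.permutation(n)
        q1 = sk.skat_statistic(sk.SkatNullModel(y, float(y.mean())), G, w)
        q2 = sk.skat_statistic(sk.SkatNullModel(y[perm], float(y.mean())), G[perm], w)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_weights_must_be_positive(self):
        null = sk.fit_null(make_manifest(2, 2))
        with pytest.raises(ValueError):
            sk.skat_statistic(null, np.ones((4, 1)), np.array([0.0]))


def mc_mixture_tail(lambdas, q, n_draws, seed):
    rng = np.random.default_rng(seed)
    draws = rng.chisquare(1, size=(n_draws, len(lambdas))) @ np.asarray(lambdas)
    return float((draws > q).mean())


class TestDaviesP:
    def test_single_eigenvalue_is_scaled_chi2(self):
        for lam, q in [(1.0, 3.84), (2.5, 10.0)]:
            p, _ = sk.davies_p(q, np.array([lam]))
            assert p == pytest.approx(stats.chi2.sf(q / lam, 1), rel=1e-8)

    def test_two_unit_eigenvalues_are_chi2_2df(self):
        p, _ = sk.davies_p(5.99, np.array([1.0, 1.0]))
        assert p == pytest.approx(stats.chi2.sf(5.99, 2), rel=1e-3)
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_against_monte_carlo_oracle(self):
        lam = np.array([2.0, 1.0, 0.5])
        p, _ = sk.davies_p(10.0, lam)
        n = 10**6
        p_mc = mc_mixture_tail(lam, 10.0, n, seed=123)
        assert abs(p - p_mc) < 3 * math.sqrt(p * (1 - p) / n)

    def test_property_random_eigenvalue_sets_match_monte_carlo(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            m = int(rng.integers(2, 9))
            lam = rng.uniform(0.2, 5.0, size=m)
            q = float(lam.sum() * rng.uniform(0.5, 2.5))
            p, _ = sk.davies_p(q, lam)
            n = 200_000
            p_mc = mc_mixture_tail(lam, q, n, seed=int(rng.integers(2**31)))
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(p - p_mc) < 4 * se + 1e-4

    def test_monotone_decreasing_in_q(self):
        lam = np.array([1.5, 1.0, 0.25])
        ps = [sk.davies_p(q, lam)[0] for q in (1.0, 5.0, 10.0, 20.0, 40.0)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_degenerate_eigenvalues(self):
        assert sk.davies_p(5.0, np.zeros(3))[0] == 1.0
        with pytest.raises(ValueError):
            sk.davies_p(5.0, np.array([-1.0, 2.0]))

    def test_liu_fallback_agrees_in_bulk(self):
        lam = np.array([3.0, 1.0, 0.4, 0.1])
        q = 8.0
        assert sk.liu_p(q, lam) == pytest.approx(sk.davies_p(q, lam)[0], abs=5e-3)


def er_enumeration_oracle(n, n_case, c, k_obs, mu):
    """Exact-rational two-sided conditional p for a singleton variant set."""
    total = math.comb(n, c)
    obs2 = (k_obs - c * mu) ** 2
    acc = Fraction(0)
    for k in range(max(0, c + n_case - n), min(c, n_case) + 1):
        if (k - c * mu) ** 2 >= obs2 - 1e-12:
            acc += Fraction(math.comb(n_case, k) * math.comb(n - n_case, c - k), total)
    return float(acc)


class TestSingleVariantErP:
    def test_three_carriers_all_cases_equals_enumeration(self, cohort_manifest):
        null = sk.fit_null(cohort_manifest)
        g = np.zeros(1541)
        g[:3] = 1  # first samples are cases
        p, method = sk.single_variant_er_p(null, g)
        assert method == "exact_resampling"
        assert p == pytest.approx(
            er_enumeration_oracle(1541, 146, 3, 3, null.mu), abs=1e-12
        )

    @pytest.mark.parametrize("n,n_case,c,k", [(30, 10, 4, 2), (50, 25, 7, 0),
                                              (200, 20, 10, 5), (12, 6, 3, 3)])
    def test_equals_enumeration_oracle(self, n, n_case, c, k):
        null = sk.fit_null(make_manifest(n_case, n - n_case))
        g = np.zeros(n)
        g[:k] = 1
        g[n_case:n_case + (c - k)] = 1
        p, method = sk.single_variant_er_p(null, g)
        assert method == "exact_resampling"
        assert p == pytest.approx(er_enumeration_oracle(n, n_case, c, k, null.mu),
                                  abs=1e-12)

    def test_monomorphic_column(self, cohort_manifest):
        null = sk.fit_null(cohort_manifest)
        assert sk.single_variant_er_p(null, np.zeros(1541))[0] == 1.0

    def test_large_carrier_count_delegates_to_asymptotic(self, cohort_manifest):
        null = sk.fit_null(cohort_manifest)
        rng = np.random.default_rng(1)
        g = (rng.random(1541) < 0.3).astype(float)
        assert g.sum() > 400
        p, method = sk.single_variant_er_p(null, g)
        assert method != "exact_resampling"
        assert 0 < p <= 1


class TestExactConditionalP:
    def test_matches_complete_label_permutation_oracle(self):
        """For a tiny cohort, the 2^c carrier-status enumeration equals a
        brute-force scan over every case/control labelling."""
        import itertools

        n, n_case = 12, 5
        null = sk.fit_null(make_manifest(n_case, n - n_case))
        rng = np.random.default_rng(13)
        G = np.zeros((n, 3))
        carriers = [0, 3, 7, 10]
        for i, j in zip(carriers, [0, 0, 1, 2]):
            G[i, j] = rng.integers(1, 3)
        w = rng.uniform(0.5, 2.0, size=3)
        p = sk.skat_exact_conditional_p(null, G, w)

        gw = G * w
        q_obs = float(((gw.T @ null.residuals) ** 2).sum())
        hits = total = 0
        for case_idx in itertools.combinations(range(n), n_case):
            y = np.zeros(n)
            y[list(case_idx)] = 1
            q = float(((gw.T @ (y - null.mu)) ** 2).sum())
            total += 1
            if q >= q_obs * (1 - 1e-12):
                hits += 1
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_singleton_variant_reduces_to_er(self, cohort_manifest):
        """On a single singleton variant the exact gene test equals the
        single-variant efficient-resampling p (same conditional null)."""
        null = sk.fit_null(cohort_manifest)
        g = np.zeros(1541)
        g[:3] = 1
        p_gene = sk.skat_exact_conditional_p(null, g[:, None], np.ones(1))
        p_sv, _ = sk.single_variant_er_p(null, g)
        # gene test is one-sided in Q = score^2, the single-variant test is
        # two-sided in the score: identical acceptance regions here
        assert p_gene == pytest.approx(p_sv, abs=1e-12)

    def test_no_carriers(self, cohort_manifest):
        null = sk.fit_null(cohort_manifest)
        assert sk.skat_exact_conditional_p(null, np.zeros((1541, 2)), np.ones(2)) == 1.0

    def test_all_case_carriers_probability(self, cohort_manifest):
        """Seven case-only carriers: p equals the hypergeometric mass of
        the all-case configuration (the unique maximal-Q state)."""
        null = sk.fit_null(cohort_manifest)
        g = np.zeros(1541)
        g[:7] = 1
        p = sk.skat_exact_conditional_p(null, g[:, None], np.ones(1))
        expected = stats.hypergeom.pmf(7, 1541, 146, 7)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p < 2.5e-6


class TestSkatTestGene:
    @staticmethod
    def _cohort(rng, n_case, n_control, mafs, plant_case_carriers=0):
        n = n_case + n_control
        G = rng.binomial(2, mafs, size=(n, len(mafs))).astype(np.int8)
        if plant_case_carriers:
            G[:plant_case_carriers, 0] = 1
        keys = [VariantKey("chr1", j + 1, "A", "G") for j in range(len(mafs))]
        manifest = make_manifest(n_case, n_control)
        geno = CohortGenotypes(manifest, keys, G)
        return geno, GeneVariantSet("G1", "NONSYN", keys)

    def test_planted_strong_enrichment_is_exome_wide(self):
        rng = np.random.default_rng(2)
        geno, gs = self._cohort(rng, 146, 1395, np.full(4, 0.002),
                                plant_case_carriers=20)
        null = sk.fit_null(geno.manifest)
        r = sk.skat_test_gene("G1", null, geno, gs)
        assert r.p_value < 2.5e-6 and r.exome_wide

    def test_single_common_variant_agrees_with_logistic_score_test(self):
        """For one variant the kernel test collapses to the 1-df score
        test; at n=5000 balanced it must track a logistic-regression
        likelihood-ratio p within 0.2 on the log10 scale."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        geno, gs = self._cohort(rng, 2500, 2500, np.array([0.3]))
        null = sk.fit_null(geno.manifest)
        r = sk.skat_test_gene("G1", null, geno, gs)
        g = geno.dosage[:, 0].astype(float)
        y = geno.manifest.case_mask().astype(float)
        fit = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
        p_lrt = stats.chi2.sf(2 * (fit.llf - sm.Logit(y, np.ones_like(y)).fit(disp=0).llf), 1)
        assert abs(np.log10(r.p_value) - np.log10(p_lrt)) < 0.2

    def test_reports_carrier_summary(self):
        rng = np.random.default_rng(3)
        geno, gs = self._cohort(rng, 50, 100, np.array([0.01, 0.02]))
        r = sk.skat_test_gene("G1", sk.fit_null(geno.manifest), geno, gs)
        assert r.table is not None and r.odds_ratio > 0
        assert r.n_variants <= 2


class TestBonferroni:
    def test_examples(self):
        assert sk.bonferroni([0.01]) == [0.01]
        assert sk.bonferroni([1e-9, 0.5]) == [2e-9, 1.0]

    def test_random_list_matches_recomputation(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0, 1, size=37).tolist()
        assert sk.bonferroni(ps) == [min(1.0, p * 37) for p in ps]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sk.bonferroni([])
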
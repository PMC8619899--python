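"""Genotype QC, HWE tests, association fits and LD pruning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gdmprs.cohort import GenotypeMatrix, VariantRecord
from gdmprs.qc import (
    AssocResult,
    QcThresholds,
    apply_qc_filters,
    association_scan,
    hwe_test,
    ld_prune,
    ld_r2,
    select_candidates,
    single_snp_logistic,
)
from gdmprs.simulate import VariantSimSpec, simulate_genotypes

from conftest import textbook_irls


def exact_hwe_enumeration(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Brute-force oracle: enumerate every heterozygote count compatible
    with the fixed allele totals and sum the probabilities of outcomes no
    more probable than the observed one."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_a = min(n_a, 2 * n - n_a)
    probs = {}
    for het in range(n_a % 2, n_a + 1, 2):
        hom_a = (n_a - het) // 2
        hom_b = n - het - hom_a
        if hom_b < 0:
            continue
        p = (
            2.0**het
            * math.factorial(n)
            / (math.factorial(hom_a) * math.factorial(het) * math.factorial(hom_b))
            * math.factorial(n_a) * math.factorial(2 * n - n_a)
            / math.factorial(2 * n)
        )
        probs[het] = p
    obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


class TestHwe:
    def test_perfect_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25, "chi2") == pytest.approx(1.0)

    def test_chi2_closed_form(self):
        """(30,40,30): statistic 4.0 against expected (25,50,25), df 1."""
        assert hwe_test(30, 40, 30, "chi2") == pytest.approx(
            stats.chi2.sf(4.0, 1), abs=1e-12)

    def test_exact_matches_enumeration_small_counts(self):
        assert hwe_test(3, 5, 12, "exact") == pytest.approx(
            exact_hwe_enumeration(3, 5, 12), rel=1e-9)

    def test_monomorphic_defined_as_one(self):
        assert hwe_test(0, 0, 50) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)

    def test_exact_and_chi2_agree_for_balanced_large_counts(self):
        for counts in [(100, 210, 110), (150, 300, 150), (120, 250, 130)]:
            assert abs(hwe_test(*counts, method="exact")
                       - hwe_test(*counts, method="chi2")) < 0.02

    def test_null_p_values_not_anticonservative(self):
        """Under HWE sampling, p-values are uniform or super-uniform:
        one-sided KS against uniform (only the anti-conservative direction
        rejects) at alpha = 0.001, 2000 replicates."""
        rng = np.random.default_rng(99)
        n, p = 100, 0.3
        pvals = []
        for _ in range(2000):
            hap = rng.binomial(1, p, (n, 2)).sum(axis=1)
            pvals.append(hwe_test(int((hap == 2).sum()), int((hap == 1).sum()),
                                  int((hap == 0).sum())))
        pvals = np.sort(pvals)
        # empirical CDF must not exceed uniform beyond the KS band
        d_plus = np.max(np.arange(1, 2001) / 2000 - pvals)
        assert d_plus < stats.kstwo.ppf(0.999, 2000)


class TestQcFilters:
    @staticmethod
    def _matrix(dosage_cols, ids=None):
        cols = np.column_stack(dosage_cols)
        variants = [VariantRecord(ids[j] if ids else f"v{j}", "1", 100 + j,
                                  "A", "G", 0.3)
                    for j in range(cols.shape[1])]
        return GenotypeMatrix(variants, cols)

    def test_missingness_exclusion_reason(self):
        rng = np.random.default_rng(1)
        good = rng.binomial(2, 0.12, 400).astype(float)
        bad = good.copy()
        bad[:20] = np.nan  # 5% missing
        gm = self._matrix([good, bad])
        kept, report = apply_qc_filters(gm)
        assert kept.variant_ids == ["v0"]
        assert report.table.loc["v1", "reason"] == "missing_rate"

    def test_het_excess_exclusion(self):
        """All-heterozygote variant (het 100%) fails the het filter; a
        50%-het HWE-consistent variant fails the default 30% rule too."""
        rng = np.random.default_rng(2)
        ok = rng.binomial(2, 0.12, 400).astype(float)
        hap = rng.binomial(1, 0.5, (400, 2)).sum(axis=1).astype(float)
        gm = self._matrix([ok, hap])
        kept, report = apply_qc_filters(gm)
        assert "het_rate" in report.table.loc["v1", "reason"]
        assert kept.variant_ids == ["v0"]

    def test_default_thresholds_equal_explicit(self):
        rng = np.random.default_rng(3)
        cols = [rng.binomial(2, q, 300).astype(float) for q in (0.1, 0.15)]
        gm = self._matrix(cols)
        k1, r1 = apply_qc_filters(gm)
        k2, r2 = apply_qc_filters(gm, QcThresholds(0.04, 0.30, 0.05))
        assert k1.variant_ids == k2.variant_ids
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_all_excluded_raises(self):
        gm = self._matrix([np.full(100, np.nan)])
        with pytest.raises(ValueError, match="every variant"):
            apply_qc_filters(gm)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QcThresholds(max_missing_rate=1.5)


class TestLogistic:
    def test_binary_recode_equals_contingency_cross_product(self):
        """With a 0/1 predictor and no covariates the fitted OR is the 2x2
        cross-product ratio."""
        rng = np.random.default_rng(4)
        x = rng.binomial(1, 0.4, 2000).astype(float)
        y = rng.binomial(1, np.where(x > 0, 0.3, 0.15))
        res = single_snp_logistic(x, y)
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        assert res.or_value == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_matches_textbook_irls_on_random_datasets(self):
        """20 random small datasets, no covariates: coefficients agree with
        an independent textbook IRLS implementation to 1e-6."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(80, 200))
            x = rng.binomial(2, rng.uniform(0.2, 0.5), n).astype(float)
            eta = -0.5 + 0.4 * x
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            if y.min() == y.max():
                continue
            res = single_snp_logistic(x, y)
            oracle = textbook_irls(np.column_stack([np.ones(n), x]), y)
            assert res.beta == pytest.approx(oracle[1], abs=1e-6)

    def test_missing_dosages_excluded_from_fit(self):
        rng = np.random.default_rng(6)
        x = rng.binomial(2, 0.3, 500).astype(float)
        y = rng.binomial(1, 0.2, 500).astype(float)
        x_missing = x.copy()
        x_missing[:50] = np.nan
        res = single_snp_logistic(x_missing, y)
        ref = single_snp_logistic(x[50:], y[50:])
        assert res.n_used == 450
        assert res.beta == pytest.approx(ref.beta, abs=1e-10)

    def test_complete_separation_flagged_not_raised(self):
        x = np.array([0.0] * 20 + [2.0] * 20)
        y = np.array([0] * 20 + [1] * 20)
        res = single_snp_logistic(x, y, variant_id="sep")
        assert res.separation and np.isinf(res.ci_high)

    def test_null_type_one_error(self):
        """Dosage independent of outcome: OR near 1 and p > 0.05 in most
        replicates (40 reps, allow up to 6 rejections)."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(40):
            x = rng.binomial(2, 0.3, 3000).astype(float)
            y = rng.binomial(1, 0.1, 3000).astype(float)
            res = single_snp_logistic(x, y)
            rejections += res.p_adjusted_model < 0.05
        assert rejections <= 6


class TestSelectCandidates:
    @staticmethod
    def _result(vid, p):
        return AssocResult(vid, 0.1, 0.05, 1.1, 1.0, 1.2, p, 100)

    def test_all_null_gives_empty(self):
        with pytest.warns(UserWarning, match="no variants"):
            assert select_candidates([self._result("a", 0.5)]) == []

    def test_strict_threshold_boundary(self):
        results = [self._result("a", 2e-5), self._result("b", 9e-5),
                   self._result("c", 1.1e-4)]
        chosen = select_candidates(results)
        assert [r.variant_id for r in chosen] == ["a", "b"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_candidates([])


class TestLdR2:
    def test_identical_vectors_r2_one(self):
        rng = np.random.default_rng(8)
        x = rng.binomial(2, 0.3, 500).astype(float)
        assert ld_r2(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_independent_variants_near_zero(self):
        gm = simulate_genotypes(
            50_000,
            [VariantSimSpec(id="a", maf=0.3), VariantSimSpec(id="b", maf=0.4)],
            seed=9,
        )
        assert ld_r2(gm.column("a"), gm.column("b")) < 0.01

    def test_em_matches_phased_haplotype_counts(self):
        """Two-locus simulation with known phase: EM r2 from unphased
        genotypes within 0.02 of the direct haplotype-count r2."""
        rng = np.random.default_rng(10)
        # haplotype freqs for MAFs 0.4/0.3 with positive D
        p_ab, p_a, p_b = 0.2, 0.4, 0.3
        f = np.array([p_ab, p_a - p_ab, p_b - p_ab, 1 - p_a - p_b + p_ab])
        hap = rng.choice(4, size=(20_000, 2), p=f)
        allele_a = (hap < 2).astype(float)
        allele_b = ((hap == 0) | (hap == 2)).astype(float)
        dos_a, dos_b = allele_a.sum(axis=1), allele_b.sum(axis=1)
        # phased oracle
        fa = allele_a.mean()
        fb = allele_b.mean()
        fab = ((hap == 0)).mean() * 2 / 2  # freq of AB haplotype
        fab = (hap == 0).sum() / hap.size
        d = fab - fa * fb
        oracle = d * d / (fa * (1 - fa) * fb * (1 - fb))
        assert ld_r2(dos_a, dos_b) == pytest.approx(oracle, abs=0.02)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(np.zeros(100), np.ones(100))


class TestLdPrune:
    @staticmethod
    def _assoc(vid, p):
        return AssocResult(vid, 0.1, 0.05, 1.1, 1.0, 1.2, p, 100)

    def test_same_chromosome_duplicate_keeps_smaller_p(self):
        rng = np.random.default_rng(11)
        x = rng.binomial(2, 0.3, 1000).astype(float)
        gm = GenotypeMatrix(
            [VariantRecord("a", "1", 100, "A", "G", 0.3),
             VariantRecord("b", "1", 200, "C", "T", 0.3)],
            np.column_stack([x, x]),
        )
        kept = ld_prune([self._assoc("a", 1e-6), self._assoc("b", 1e-5)], gm)
        assert [r.variant_id for r in kept] == ["a"]

    def test_cross_chromosome_pair_never_tested(self):
        rng = np.random.default_rng(12)
        x = rng.binomial(2, 0.3, 1000).astype(float)
        gm = GenotypeMatrix(
            [VariantRecord("a", "1", 100, "A", "G", 0.3),
             VariantRecord("b", "2", 100, "C", "T", 0.3)],
            np.column_stack([x, x]),
        )
        kept = ld_prune([self._assoc("a", 1e-6), self._assoc("b", 1e-5)], gm)
        assert [r.variant_id for r in kept] == ["a", "b"]

    def test_greedy_chain_hand_trace(self):
        """A-B r2 0.5, B-C r2 0.5, A-C r2 0.1, p order A<B<C: keep {A, C}."""
        specs = [
            VariantSimSpec(id="A", maf=0.4),
            VariantSimSpec(id="B", maf=0.4, ld_with="A", ld_r2=0.5),
            VariantSimSpec(id="C", maf=0.4, ld_with="B", ld_r2=0.5),
        ]
        gm = simulate_genotypes(100_000, specs, seed=13)
        assert ld_r2(gm.column("A"), gm.column("C")) < 0.3  # ~0.25 expected
        kept = ld_prune(
            [self._assoc("A", 1e-7), self._assoc("B", 1e-6), self._assoc("C", 1e-5)],
            gm,
        )
        assert [r.variant_id for r in kept] == ["A", "C"]

    def test_output_pairwise_r2_below_threshold(self):
        specs = [VariantSimSpec(id=f"v{i}", maf=0.3) for i in range(4)]
        specs += [VariantSimSpec(id="v4", maf=0.3, ld_with="v0", ld_r2=0.8)]
        gm = simulate_genotypes(20_000, specs, seed=14)
        results = [self._assoc(v, 10**-(6 - i)) for i, v in
                   enumerate(["v0", "v1", "v2", "v3", "v4"])]
        kept = ld_prune(results, gm, r2_threshold=0.3)
        for r1, r2 in itertools.combinations(kept, 2):
            assert ld_r2(gm.column(r1.variant_id),
                         gm.column(r2.variant_id)) <= 0.3
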
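"""GMDR: score residuals, cell classification, CV search and sign test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gdmprs.cohort import GenotypeMatrix, VariantRecord
from gdmprs.gmdr import (
    ScoreVector,
    compute_score_residuals,
    evaluate_model,
    run_gmdr_search,
    sign_test,
    stratified_folds,
)
from gdmprs.simulate import (
    PenetranceSpec,
    VariantSimSpec,
    simulate_covariates,
    simulate_gdm,
    simulate_genotypes,
)


def brute_force_balanced_accuracy(dosages, scores, y, train_idx, test_idx,
                                  threshold=0.0):
    """Independent cell-dictionary reimplementation: walk training subjects,
    accumulate per-genotype-tuple score sums, label cells, then score
    train/test sets subject by subject."""
    sums: dict[tuple, float] = {}
    for i in train_idx:
        row = tuple(dosages[i])
        if any(np.isnan(v) for v in row):
            continue
        sums[row] = sums.get(row, 0.0) + scores[i]

    def ba(idx):
        tp = fn = tn = fp = 0
        for i in idx:
            row = tuple(dosages[i])
            if any(np.isnan(v) for v in row):
                continue
            high = sums.get(row, 0.0) > threshold
            if y[i] == 1:
                tp, fn = tp + high, fn + (not high)
            else:
                fp, tn = fp + high, tn + (not high)
        if tp + fn == 0 or tn + fp == 0:
            return float("nan")
        return 0.5 * (tp / (tp + fn) + tn / (tn + fp))

    return ba(train_idx), ba(test_idx)


def _random_instance(rng, n, k):
    mafs = rng.uniform(0.2, 0.5, k)
    variants = [VariantRecord(f"v{j}", "1", 100 + j, "A", "G", float(mafs[j]))
                for j in range(k)]
    dosages = rng.binomial(2, mafs, size=(n, k)).astype(float)
    # sprinkle missing calls
    miss = rng.random((n, k)) < 0.05
    dosages[miss] = np.nan
    y = rng.binomial(1, 0.4, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    gm = GenotypeMatrix(variants, dosages)
    return gm, y


class TestScoreResiduals:
    def test_intercept_only_closed_form(self):
        """30 cases / 70 controls: scores are 0.7 and -0.3, summing to 0."""
        y = np.array([1] * 30 + [0] * 70)
        sv = compute_score_residuals(y)
        np.testing.assert_allclose(sv.scores[:30], 0.7)
        np.testing.assert_allclose(sv.scores[30:], -0.3)
        assert abs(sv.scores.sum()) < 1e-6

    def test_scores_sum_to_zero_with_covariates(self):
        rng = np.random.default_rng(1)
        y = rng.binomial(1, 0.3, 500)
        cov = pd.DataFrame({"x1": rng.normal(size=500),
                            "grp": rng.choice(["a", "b", "c"], 500)})
        sv = compute_score_residuals(y, cov)
        assert abs(sv.scores.sum()) < 1e-6

    def test_single_binary_covariate_stratum_prevalence(self):
        """Saturated binary covariate: fitted p equals stratum prevalence."""
        y = np.array([1] * 10 + [0] * 40 + [1] * 30 + [0] * 20)
        cov = pd.DataFrame({"z": [0.0] * 50 + [1.0] * 50})
        sv = compute_score_residuals(y, cov)
        np.testing.assert_allclose(sv.scores[:50], y[:50] - 0.2, atol=1e-6)
        np.testing.assert_allclose(sv.scores[50:], y[50:] - 0.6, atol=1e-6)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_score_residuals(np.zeros(10))


class TestEvaluateModel:
    def test_perfectly_separating_single_snp(self):
        variants = [VariantRecord("v", "1", 1, "A", "G", 0.5)]
        dosages = np.array([[2.0]] * 10 + [[0.0]] * 10)
        gm = GenotypeMatrix(variants, dosages)
        y = np.array([1] * 10 + [0] * 10)
        sv = compute_score_residuals(y)
        idx = np.arange(20)
        trba, _, labels = evaluate_model(["v"], sv, gm, idx, np.array([], int))
        assert trba == 1.0
        assert labels[(2,)] == "high" and labels[(0,)] == "low"

    def test_matches_brute_force_oracle(self):
        """evaluate_model equals the independent cell-dictionary oracle on
        random instances with missing calls (30 instances here; the full
        100-instance sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(20, 51))
            k = int(rng.integers(1, 4))
            gm, y = _random_instance(rng, n, k)
            sv = compute_score_residuals(y)
            perm = rng.permutation(n)
            train, test = perm[: int(0.7 * n)], perm[int(0.7 * n):]
            trba, teba, _ = evaluate_model(gm.variant_ids, sv, gm, train, test)
            otr, ote = brute_force_balanced_accuracy(
                gm.dosages, sv.scores, y, train, test)
            assert trba == pytest.approx(otr, abs=1e-10, nan_ok=True)
            assert teba == pytest.approx(ote, abs=1e-10, nan_ok=True)

    def test_permuted_labels_give_chance_test_accuracy(self):
        """Random outcome permutations: mean test BA ~ 0.5 (50 permutations,
        n = 2000)."""
        rng = np.random.default_rng(3)
        gm = simulate_genotypes(
            2000, [VariantSimSpec(id="a", maf=0.3),
                   VariantSimSpec(id="b", maf=0.4)], seed=4)
        y0 = rng.binomial(1, 0.3, 2000)
        tebas = []
        for _ in range(50):
            y = rng.permutation(y0)
            sv = compute_score_residuals(y)
            perm = rng.permutation(2000)
            train, test = perm[:1400], perm[1400:]
            _, teba, _ = evaluate_model(["a", "b"], sv, gm, train, test)
            tebas.append(teba)
        assert abs(np.mean(tebas) - 0.5) < 0.02

    def test_overlapping_train_test_rejected(self):
        gm = simulate_genotypes(50, [VariantSimSpec(id="a", maf=0.3)], 5)
        y = np.array([1, 0] * 25)
        sv = compute_score_residuals(y)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_model(["a"], sv, gm, np.arange(30), np.arange(25, 50))


class TestSignTest:
    @pytest.mark.parametrize("stat,expected", [
        (4, 0.828), (6, 0.377), (8, 0.055), (9, 0.011), (10, 0.001)])
    def test_ten_fold_binomial_tail(self, stat, expected):
        assert round(sign_test(stat, 10), 3) == expected

    def test_zero_statistic_full_tail(self):
        assert sign_test(0, 10) == 1.0

    def test_monotone_decreasing_in_statistic(self):
        ps = [sign_test(s, 10) for s in range(11)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sign_test(11, 10)


class TestSearch:
    def test_k_larger_than_candidates_rejected(self):
        gm = simulate_genotypes(100, [VariantSimSpec(id="a", maf=0.3)], 6)
        y = np.array([1, 0] * 50)
        sv = compute_score_residuals(y)
        with pytest.raises(ValueError, match="exceeds"):
            run_gmdr_search(["a"], sv, gm, k_range=[2])

    def test_fixed_seed_reproducible(self):
        specs = [VariantSimSpec(id=f"v{i}", maf=0.3) for i in range(4)]
        gm = simulate_genotypes(1000, specs, 7)
        rng = np.random.default_rng(8)
        y = rng.binomial(1, 0.2, 1000)
        sv = compute_score_residuals(y)
        r1 = run_gmdr_search(gm.variant_ids, sv, gm, k_range=[1, 2], seed=5)
        r2 = run_gmdr_search(gm.variant_ids, sv, gm, k_range=[1, 2], seed=5)
        for a, b in zip(r1, r2):
            assert a.snp_ids == b.snp_ids
            assert a.fold_train_ba == b.fold_train_ba
            assert a.fold_test_ba == b.fold_test_ba
            assert (a.cvc, a.sign_stat) == (b.cvc, b.sign_stat)

    def test_training_accuracy_monotone_in_subset_size(self):
        """Best-of-size mean TRBA never decreases with k on a fixed dataset:
        richer partitions can only fit training data better."""
        specs = [VariantSimSpec(id=f"v{i}", maf=0.35) for i in range(5)]
        gm = simulate_genotypes(2000, specs, 9)
        rng = np.random.default_rng(10)
        y = rng.binomial(1, 0.15, 2000)
        sv = compute_score_residuals(y)
        results = run_gmdr_search(gm.variant_ids, sv, gm, k_range=[1, 2, 3], seed=1)
        trbas = [r.trba for r in results]
        assert trbas == sorted(trbas)

    def test_stratified_folds_balance_cases(self):
        y = np.array([1] * 40 + [0] * 360)
        fold = stratified_folds(y, 10, seed=3)
        for f in range(10):
            assert (y[fold == f] == 1).sum() == 4

    def test_recovers_strong_planted_pair(self):
        """A strong planted epistatic pair among nulls is the best 2-SNP
        model with full cross-validation consistency."""
        specs = [VariantSimSpec(id=f"null{i}", maf=0.3) for i in range(4)]
        specs += [VariantSimSpec(id="epiA", maf=0.4),
                  VariantSimSpec(id="epiB", maf=0.4)]
        gm = simulate_genotypes(6000, specs, 11)
        pen = PenetranceSpec(model_snps=["epiA", "epiB"],
                             epistasis_terms=[("epiA", "epiB", 2.0)])
        cov = simulate_covariates(6000, 12)
        ph = simulate_gdm(gm, pen, cov, 13)
        sv = compute_score_residuals(ph.data["gdm_status"].to_numpy())
        res = run_gmdr_search(gm.variant_ids, sv, gm, k_range=[2], seed=14)[0]
        assert set(res.snp_ids) == {"epiA", "epiB"}
        assert res.cvc == 10
        assert res.sign_p <= 0.011
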
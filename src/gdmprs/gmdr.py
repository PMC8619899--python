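"""Generalized multifactor dimensionality reduction (GMDR).

GMDR screens SNP subsets for joint (epistatic) effects on a binary outcome.
Each subject is first reduced to a score residual ``y - p_hat`` from a
covariate-only logistic null model; a candidate k-SNP subset partitions
subjects into its 3^k multilocus genotype cells, and a cell is labelled
high-risk when the summed training scores in it exceed a threshold (default
0).  The induced high/low classification is evaluated by balanced accuracy
— the mean of sensitivity and specificity against the observed outcome — on
training (TRBA) and held-out (TEBA) folds of a stratified 10-fold
cross-validation.  The best model of each size is the subset winning the
most folds by training balanced accuracy; its cross-validation consistency
(CVC) is the number of folds won, and a one-sided binomial sign test on the
number of folds whose test balanced accuracy beats 0.5 gauges significance.

Cells unseen in training, and cells whose training scores sum to exactly the
threshold, are labelled low-risk (a deterministic, conservative rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import GenotypeMatrix
from .qc import build_design

__all__ = [
    "ScoreVector",
    "GmdrModelResult",
    "compute_score_residuals",
    "evaluate_model",
    "run_gmdr_search",
    "sign_test",
    "stratified_folds",
]


@dataclass
class ScoreVector:
    """Per-subject GMDR score residuals with the outcome they came from."""

    scores: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.scores.shape != self.outcome.shape:
            raise ValueError("scores and outcome must be aligned")


def compute_score_residuals(
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> ScoreVector:
    """Score residuals ``y - p_hat`` from the covariate-only logistic null.

    With no covariates the fit reduces to the intercept-only model, so the
    residuals are ``y - mean(y)``.  Because the null model contains an
    intercept, the residuals sum to zero.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if isinstance(covariates, pd.DataFrame):
        covariates = build_design(covariates)
    if covariates is None or np.size(covariates) == 0:
        fitted = np.full_like(y, y.mean())
    else:
        design = np.column_stack([np.ones_like(y), np.asarray(covariates, float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200, tol=1e-10)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError(
                "null model did not converge (covariates may separate the outcome)"
            )
        fitted = fit.predict(design)
    return ScoreVector(scores=y - fitted, outcome=y.astype(int))


def _cell_codes(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map each subject to a base-3 multilocus cell; missing rows flagged."""
    valid = ~np.isnan(dosages).any(axis=1)
    codes = np.zeros(dosages.shape[0], dtype=np.int64)
    for i in range(dosages.shape[1]):
        codes = codes * 3 + np.nan_to_num(dosages[:, i]).astype(np.int64)
    return codes, valid


def _balanced_accuracy(pred_high: np.ndarray, y: np.ndarray) -> float:
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        return float("nan")
    sens = pred_high[y == 1].sum() / n_case
    spec = (~pred_high[y == 0]).sum() / n_ctrl
    return float(0.5 * (sens + spec))


def evaluate_model(
    snp_subset: Sequence[str],
    scores: ScoreVector,
    genotypes: GenotypeMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    threshold: float = 0.0,
) -> tuple[float, float, dict[tuple[int, ...], str]]:
    """Evaluate one SNP subset on a train/test split.

    Returns (training balanced accuracy, testing balanced accuracy,
    cell-label map).  Subjects missing any subset genotype are excluded.
    Cells unseen in training are low-risk.  A split whose test set holds a
    single outcome class yields ``nan`` test balanced accuracy.
    """
    if not 1 <= len(snp_subset) <= 10:
        raise ValueError("subset size must be between 1 and 10")
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    sub = genotypes.subset(snp_subset)
    codes, valid = _cell_codes(sub.dosages)
    n_cells = 3 ** len(snp_subset)
    y = scores.outcome

    tr = train_idx[valid[train_idx]]
    te = test_idx[valid[test_idx]]
    sums = np.bincount(codes[tr], weights=scores.scores[tr], minlength=n_cells)
    high = sums > threshold
    trba = _balanced_accuracy(high[codes[tr]], y[tr])
    teba = _balanced_accuracy(high[codes[te]], y[te])
    if len(te) and np.isnan(teba):
        warnings.warn("test split contains a single outcome class; TEBA undefined")

    k = len(snp_subset)
    labels = {}
    for cell in range(n_cells):
        geno = tuple((cell // 3 ** (k - 1 - i)) % 3 for i in range(k))
        labels[geno] = "high" if high[cell] else "low"
    return trba, teba, labels


def stratified_folds(outcome: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Seeded case/control-stratified fold assignment (values 0..n_folds-1)."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    y = np.asarray(outcome)
    fold = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


@dataclass
class GmdrModelResult:
    """Best model of one subset size: the columns of a GMDR report row."""

    snp_ids: tuple[str, ...]
    trba: float
    teba: float
    sign_stat: int
    sign_p: float
    cvc: int
    n_folds: int
    cell_labels: dict[tuple[int, ...], str] = field(default_factory=dict)
    fold_train_ba: tuple[float, ...] = ()
    fold_test_ba: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.cvc <= self.n_folds):
            raise ValueError("CVC out of range")
        if not (0 <= self.sign_stat <= self.n_folds):
            raise ValueError("sign statistic out of range")


def sign_test(sign_stat: int, n_folds: int) -> float:
    """One-sided binomial tail: P(Binomial(n_folds, 1/2) >= sign_stat)."""
    if not 0 <= sign_stat <= n_folds:
        raise ValueError("sign statistic must be between 0 and n_folds")
    return float(stats.binom.sf(sign_stat - 1, n_folds, 0.5))


def _fold_stats(codes, valid, scores, y, fold, n_folds, n_cells, threshold):
    """Per-fold train/test balanced accuracy for one subset's cell codes."""
    trba = np.empty(n_folds)
    teba = np.empty(n_folds)
    v_codes = codes[valid]
    v_scores = scores[valid]
    v_y = y[valid]
    v_fold = fold[valid]
    total_sums = np.bincount(v_codes, weights=v_scores, minlength=n_cells)
    case_counts_tot = np.bincount(v_codes[v_y == 1], minlength=n_cells)
    ctrl_counts_tot = np.bincount(v_codes[v_y == 0], minlength=n_cells)
    for f in range(n_folds):
        te_mask = v_fold == f
        te_codes = v_codes[te_mask]
        te_y = v_y[te_mask]
        sums = total_sums - np.bincount(te_codes, weights=v_scores[te_mask],
                                        minlength=n_cells)
        case_te = np.bincount(te_codes[te_y == 1], minlength=n_cells)
        ctrl_te = np.bincount(te_codes[te_y == 0], minlength=n_cells)
        high = sums > threshold
        case_tr = case_counts_tot - case_te
        ctrl_tr = ctrl_counts_tot - ctrl_te
        n_case_tr, n_ctrl_tr = case_tr.sum(), ctrl_tr.sum()
        n_case_te, n_ctrl_te = case_te.sum(), ctrl_te.sum()
        if n_case_tr and n_ctrl_tr:
            trba[f] = 0.5 * (case_tr[high].sum() / n_case_tr
                             + ctrl_tr[~high].sum() / n_ctrl_tr)
        else:
            trba[f] = np.nan
        if n_case_te and n_ctrl_te:
            teba[f] = 0.5 * (case_te[high].sum() / n_case_te
                             + ctrl_te[~high].sum() / n_ctrl_te)
        else:
            teba[f] = np.nan
    return trba, teba


def run_gmdr_search(
    candidates: Sequence[str],
    scores: ScoreVector,
    genotypes: GenotypeMatrix,
    k_range: Iterable[int] = range(1, 11),
    n_folds: int = 10,
    seed: int = 0,
    threshold: float = 0.0,
) -> list[GmdrModelResult]:
    """Exhaustive GMDR search: the best model for each subset size.

    For each k, every C(len(candidates), k) subset is scored in every fold;
    the subset with the highest training balanced accuracy wins the fold,
    and the subset winning the most folds is reported (ties broken by higher
    mean test balanced accuracy, then lexicographic SNP ids).  Its CVC is
    the number of folds won; TRBA/TEBA are across-fold means; the sign
    statistic counts folds whose test balanced accuracy exceeds 0.5.
    """
    candidates = list(candidates)
    k_range = sorted(set(k_range))
    if not candidates:
        raise ValueError("empty candidate list")
    if max(k_range) > len(candidates):
        raise ValueError(
            f"subset size {max(k_range)} exceeds {len(candidates)} candidates"
        )
    y = scores.outcome
    fold = stratified_folds(y, n_folds, seed)
    all_idx = np.arange(len(y))

    results = []
    for k in k_range:
        n_cells = 3**k
        stats_by_subset: dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]] = {}
        for subset in combinations(candidates, k):
            sub = genotypes.subset(subset)
            codes, valid = _cell_codes(sub.dosages)
            stats_by_subset[subset] = _fold_stats(
                codes, valid, scores.scores, y, fold, n_folds, n_cells, threshold
            )
        subsets = list(stats_by_subset)
        trba_mat = np.array([stats_by_subset[s][0] for s in subsets])
        teba_mat = np.array([stats_by_subset[s][1] for s in subsets])
        winners = np.nanargmax(trba_mat, axis=0)  # fold winner by training BA
        wins = np.bincount(winners, minlength=len(subsets))
        best_wins = wins.max()
        tied = [i for i in range(len(subsets)) if wins[i] == best_wins]
        best_i = min(
            tied,
            key=lambda i: (-np.nanmean(teba_mat[i]), subsets[i]),
        )
        best = subsets[best_i]
        fold_trba, fold_teba = stats_by_subset[best]
        sign_stat = int(np.nansum(fold_teba > 0.5))
        # labels refit on the full cohort for reporting
        _, _, labels = evaluate_model(
            best, scores, genotypes, all_idx, np.array([], dtype=int), threshold
        )
        results.append(
            GmdrModelResult(
                snp_ids=best,
                trba=float(np.nanmean(fold_trba)),
                teba=float(np.nanmean(fold_teba)),
                sign_stat=sign_stat,
                sign_p=sign_test(sign_stat, n_folds),
                cvc=int(best_wins),
                n_folds=n_folds,
                cell_labels=labels,
                fold_train_ba=tuple(fold_trba),
                fold_test_ba=tuple(fold_teba),
            )
        )
    return results


def results_table(results: list[GmdrModelResult]) -> pd.DataFrame:
    """GMDR report: one row per subset size, sign test printed as 'stat (p)'."""
    rows = [
        dict(
            model=" + ".join(r.snp_ids),
            k=len(r.snp_ids),
            TRBA=round(r.trba, 3),
            TEBA=round(r.teba, 3),
            sign_test=f"{r.sign_stat} ({r.sign_p:.3f})",
            CVC=f"{r.cvc}/{r.n_folds}",
        )
        for r in results
    ]
    return pd.DataFrame(rows)
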
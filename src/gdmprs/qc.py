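"""Genotype quality control, single-SNP association and LD pruning.

QC keeps a variant when its missing call rate is < 4%, its heterozygote
fraction is < 30% and its Hardy-Weinberg equilibrium p-value exceeds 0.05
(all thresholds configurable).  Association is a covariate-adjusted additive
(allele-dosage) logistic regression; candidates are taken below a p-value
threshold (default 1e-4) and thinned by greedy same-chromosome LD pruning at
r-squared > 0.3, with haplotype frequencies estimated by EM from unphased
two-locus genotype counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .cohort import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "AssocResult",
    "hwe_test",
    "apply_qc_filters",
    "single_snp_logistic",
    "association_scan",
    "select_candidates",
    "ld_r2",
    "ld_prune",
    "build_design",
]


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def _hwe_chi2(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (expected <= 0).any():
        return 1.0  # monomorphic: no test possible
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=1))


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Conditional exact test: sum P over heterozygote counts no more
    probable than the observed one, with allele totals fixed."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab  # minor-allele count
    if n_a > n:  # orient to the rarer allele
        n_a = 2 * n - n_a
    if n_a == 0:
        return 1.0
    hets = np.arange(n_a % 2, n_a + 1, 2)
    homs_a = (n_a - hets) // 2
    homs_b = n - hets - homs_a
    # log P(n_ab = h | n, n_a) up to a constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homs_a + 1)
        - gammaln(homs_b + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    observed = prob[hets == n_ab][0]
    return float(prob[prob <= observed * (1 + 1e-12)].sum())


def hwe_test(n_aa: int, n_ab: int, n_bb: int, method: str = "auto") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    Counts are (hom-minor, het, hom-major).  ``method``: ``"chi2"`` for the
    1-df goodness-of-fit test against (p^2, 2pq, q^2), ``"exact"`` for the
    conditional exact test, or ``"auto"`` (exact when the smallest expected
    genotype count is below 5).  Monomorphic input returns p = 1.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype observations")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    if method == "auto":
        q = 1.0 - p
        min_expected = n * min(p * p, 2 * p * q, q * q)
        method = "exact" if min_expected < 5 else "chi2"
    if method == "chi2":
        return _hwe_chi2(n_aa, n_ab, n_bb)
    if method == "exact":
        return _hwe_exact(n_aa, n_ab, n_bb)
    raise ValueError(f"unknown HWE method {method!r}")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """Variant-level QC thresholds (defaults are the standard chip criteria)."""

    max_missing_rate: float = 0.04
    max_het_rate: float = 0.30
    min_hwe_p: float = 0.05
    hwe_method: str = "auto"

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "max_het_rate", "min_hwe_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class QcReport:
    """Per-variant QC metrics, pass flags and exclusion reasons."""

    table: pd.DataFrame
    thresholds: QcThresholds

    @property
    def passed_ids(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])

    @property
    def exclusions(self) -> pd.DataFrame:
        return self.table[~self.table["pass"]]


def apply_qc_filters(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants failing missingness, heterozygosity or HWE checks.

    HWE is tested on non-missing genotype counts.  Raises if every variant
    is excluded.
    """
    thr = thresholds or QcThresholds()
    miss = genotypes.missing_rate()
    het = genotypes.het_rate()
    maf = genotypes.observed_maf()
    rows = []
    for j, v in enumerate(genotypes.variants):
        col = genotypes.dosages[:, j]
        n_aa = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 0).sum())
        # an all-missing variant has no testable genotypes; the missingness
        # filter is what excludes it
        hwe_p = (1.0 if n_aa + n_ab + n_bb == 0
                 else hwe_test(n_aa, n_ab, n_bb, method=thr.hwe_method))
        reasons = []
        if not miss[j] < thr.max_missing_rate:
            reasons.append("missing_rate")
        if not het[j] < thr.max_het_rate:
            reasons.append("het_rate")
        if not hwe_p > thr.min_hwe_p:
            reasons.append("hwe_p")
        rows.append(
            dict(id=v.id, missing_rate=miss[j], het_rate=het[j],
                 hwe_p=hwe_p, maf=maf[j], pass_=not reasons,
                 reason=";".join(reasons))
        )
    table = pd.DataFrame(rows).set_index("id").rename(columns={"pass_": "pass"})
    report = QcReport(table=table, thresholds=thr)
    kept = report.passed_ids
    if not kept:
        raise ValueError("QC excluded every variant")
    return genotypes.subset(kept), report


# ---------------------------------------------------------------------------
# Single-SNP association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssocResult:
    """Covariate-adjusted additive logistic association for one variant."""

    variant_id: str
    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    p_adjusted_model: float
    n_used: int
    separation: bool = False

    def __post_init__(self) -> None:
        if not self.separation and not (
            self.ci_low <= self.or_value <= self.ci_high
        ):
            raise ValueError("CI does not bracket the odds ratio")


def build_design(covariates: pd.DataFrame | None) -> np.ndarray | None:
    """Dummy-code object columns, pass numeric through; no intercept."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
        else:
            parts.append(s.astype(float).to_frame())
    return pd.concat(parts, axis=1).to_numpy()


def single_snp_logistic(
    dosages: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variant_id: str = "",
    maxiter: int = 100,
) -> AssocResult:
    """Additive logistic regression of a binary outcome on one dosage.

    Subjects with a missing dosage are dropped.  Returns the per-minor-allele
    log-OR with Wald 95% CI ``exp(beta +/- 1.96 se)``.  Complete separation
    is flagged (infinite CI) rather than raised.
    """
    dosages = np.asarray(dosages, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        covariates = build_design(covariates)
    keep = ~np.isnan(dosages)
    x, y = dosages[keep], outcome[keep]
    if len(np.unique(y)) < 2:
        raise ValueError(f"{variant_id}: outcome has a single class")
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[keep]
        cols.extend(cov.T)
    design = np.column_stack(cols)
    # drop aliased covariate columns (never the intercept or the dosage)
    rank_keep = _independent_columns(design)
    design = design[:, rank_keep]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        try:
            fit = model.fit(disp=0, maxiter=maxiter, tol=1e-8)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            # complete/quasi-complete separation: flag with an infinite CI
            sign = np.sign(np.corrcoef(x, y)[0, 1]) or 1.0
            return AssocResult(variant_id, float(sign * np.inf), float("inf"),
                               float("inf") if sign > 0 else 0.0,
                               0.0, float("inf"), 1.0, int(keep.sum()),
                               separation=True)
        except Exception as exc:
            raise RuntimeError(f"{variant_id}: logistic fit failed: {exc}") from exc
    beta = fit.params[1]
    se = fit.bse[1]
    separated = not np.isfinite(se) or se > 50 or not fit.mle_retvals.get("converged", True)
    if separated and abs(beta) < 20:
        raise RuntimeError(f"{variant_id}: logistic fit did not converge")
    if separated:
        return AssocResult(variant_id, float(beta), float("inf"), float(np.exp(beta)),
                           0.0, float("inf"), 1.0, int(keep.sum()), separation=True)
    ci_low, ci_high = np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se)
    return AssocResult(
        variant_id=variant_id, beta=float(beta), se=float(se),
        or_value=float(np.exp(beta)), ci_low=float(ci_low), ci_high=float(ci_high),
        p_adjusted_model=float(fit.pvalues[1]), n_used=int(keep.sum()),
    )


def _independent_columns(design: np.ndarray) -> list[int]:
    keep: list[int] = []
    for j in range(design.shape[1]):
        trial = design[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return keep


def association_scan(
    genotypes: GenotypeMatrix,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> list[AssocResult]:
    """Run :func:`single_snp_logistic` over every variant."""
    design = build_design(covariates) if covariates is not None else None
    return [
        single_snp_logistic(genotypes.dosages[:, j], outcome, design,
                            variant_id=v.id)
        for j, v in enumerate(genotypes.variants)
    ]


def select_candidates(
    results: list[AssocResult],
    p_threshold: float = 1e-4,
) -> list[AssocResult]:
    """Variants with adjusted p strictly below threshold, ascending by p."""
    if not results:
        raise ValueError("no association results to select from")
    chosen = sorted(
        (r for r in results if r.p_adjusted_model < p_threshold),
        key=lambda r: r.p_adjusted_model,
    )
    if not chosen:
        warnings.warn("no variants below the association p-value threshold")
    return chosen


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(
    dosages_a: np.ndarray,
    dosages_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """Squared allelic correlation from unphased genotypes via the EM
    algorithm for two-locus haplotype frequencies.

    Only the double-heterozygote class has ambiguous phase; EM splits its
    count between the cis and trans configurations until the haplotype
    frequencies converge.  r^2 = D^2 / (pA qA pB qB).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    if n == 0:
        raise ValueError("no jointly observed genotypes")
    p_a = a.mean() / 2.0
    p_b = b.mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("r2 undefined for a monomorphic variant")

    # 3x3 genotype count table
    counts = np.zeros((3, 3))
    for ga in (0, 1, 2):
        for gb in (0, 1, 2):
            counts[ga, gb] = np.count_nonzero((a == ga) & (b == gb))

    # haplotypes: AB, Ab, aB, ab where A/B are the counted (minor) alleles
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                  (1 - p_a) * (1 - p_b)])
    dh = counts[1, 1]  # double heterozygotes
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        frac_cis = 0.5 if cis + trans == 0 else cis / (cis + trans)
        n_ab_hap = (
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + dh * frac_cis
        )
        n_a_b = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + dh * (1 - frac_cis)
        n_na_b = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2] + dh * (1 - frac_cis)
        n_na_nb = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + dh * frac_cis
        new = np.array([n_ab_hap, n_a_b, n_na_b, n_na_nb]) / (2.0 * n)
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    d = f[0] - (f[0] + f[1]) * (f[0] + f[2])
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    return float(min(1.0, d * d / denom))


def ld_prune(
    candidates: list[AssocResult],
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.3,
) -> list[AssocResult]:
    """Greedy LD pruning of a p-sorted candidate list.

    Scanning in order of ascending association p (ties broken by position),
    a variant is kept iff its EM r^2 with every already-kept variant on the
    same chromosome is <= threshold.  Cross-chromosome pairs are never
    tested.
    """
    ordered = sorted(
        candidates,
        key=lambda r: (r.p_adjusted_model, genotypes.variant(r.variant_id).pos),
    )
    kept: list[AssocResult] = []
    for cand in ordered:
        v = genotypes.variant(cand.variant_id)
        ok = True
        for prev in kept:
            pv = genotypes.variant(prev.variant_id)
            if pv.chrom != v.chrom:
                continue
            r2 = ld_r2(genotypes.column(cand.variant_id),
                       genotypes.column(prev.variant_id))
            if r2 > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(cand)
    return kept
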
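"""Risk-allele polygenic risk score (PRS) over a selected SNP model.

The score is the unweighted count of risk alleles across the model SNPs: a
subject homozygous for the risk allele at a SNP contributes 2, a
heterozygote 1, a non-carrier 0 (e.g. with G the risk allele, TT/GT/GG score
0/1/2).  With a 5-SNP model the score ranges over 0..10 and is grouped into
Low (<= 3), Medium (4-5) and High (>= 6) categories by default; a tertile
mode is available.  The risk allele of each SNP is the allele whose
association odds ratio exceeds 1, which may be either the minor or the major
allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import GenotypeMatrix
from .qc import AssocResult, build_design, single_snp_logistic

__all__ = [
    "PrsModel",
    "PrsProfile",
    "count_risk_alleles",
    "compute_prs",
    "categorize_prs",
    "categorize_prs_series",
    "prs_association",
    "risk_alleles_from_association",
    "COVARIATE_PRESETS",
]

PRS_CATEGORIES = ("Low", "Medium", "High")

#: Named covariate presets.  The two "methods" presets follow the written
#: model definitions (model 1: age at first pregnancy, BMI at 20, residence
#: area; model 2 adds childbirth experience and education); the two
#: "figure" presets follow the alternative listing used for the PRS odds
#: ratio figure (model 1: age, BMI at 20, residence area, education,
#: income; model 2 adds energy intake, alcohol, smoking, exercise).
COVARIATE_PRESETS: dict[str, list[str]] = {
    "model1": ["age_first_pregnancy", "bmi_at_20", "residence_area"],
    "model2": ["age_first_pregnancy", "bmi_at_20", "residence_area",
               "childbirth", "education"],
    "model1_figure": ["age", "bmi_at_20", "residence_area", "education", "income"],
    "model2_figure": ["age", "bmi_at_20", "residence_area", "education", "income",
                      "energy_intake", "alcohol", "smoking", "exercise"],
}


@dataclass(frozen=True)
class PrsModel:
    """A PRS model: ordered SNP ids with each SNP's risk allele."""

    snp_ids: tuple[str, ...]
    risk_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.risk_alleles):
            raise ValueError("one risk allele per SNP required")


@dataclass
class PrsProfile:
    """Per-subject risk-allele counts and Low/Medium/High categories."""

    table: pd.DataFrame  # columns: prs, category

    @property
    def prs(self) -> pd.Series:
        return self.table["prs"]

    @property
    def category(self) -> pd.Series:
        return self.table["category"]


def count_risk_alleles(genotype: str, risk_allele: str) -> int:
    """Copies of the risk allele in an unordered allele pair, e.g.
    ``count_risk_alleles("GT", "G") == 1``."""
    if len(genotype) != 2:
        raise ValueError(f"genotype must be an allele pair, got {genotype!r}")
    return sum(1 for a in genotype if a == risk_allele)


def risk_alleles_from_association(
    genotypes: GenotypeMatrix,
    assoc: dict[str, AssocResult] | list[AssocResult],
    snp_ids: list[str] | tuple[str, ...],
) -> PrsModel:
    """Orient risk alleles from association results: the minor allele is the
    risk allele when its OR > 1, otherwise the major allele."""
    if isinstance(assoc, list):
        assoc = {r.variant_id: r for r in assoc}
    risk = []
    for sid in snp_ids:
        v = genotypes.variant(sid)
        r = assoc[sid]
        risk.append(v.minor_allele if r.or_value > 1.0 else v.major_allele)
    return PrsModel(snp_ids=tuple(snp_ids), risk_alleles=tuple(risk))


def compute_prs(
    genotypes: GenotypeMatrix,
    model: PrsModel,
    missing_policy: str = "exclude",
) -> PrsProfile:
    """Sum risk-allele counts over the model SNPs for every subject.

    ``missing_policy="exclude"`` leaves subjects with any missing model
    genotype without a score (NaN); ``"mean_impute"`` substitutes the
    per-variant mean risk count, yielding a real-valued (non-integer) score
    for the affected subjects.
    """
    if missing_policy not in {"exclude", "mean_impute"}:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    counts = np.zeros((genotypes.n_subjects, len(model.snp_ids)))
    for j, (sid, risk) in enumerate(zip(model.snp_ids, model.risk_alleles)):
        v = genotypes.variant(sid)
        dos = genotypes.column(sid)
        if risk == v.minor_allele:
            c = dos
        elif risk == v.major_allele:
            c = 2.0 - dos
        else:
            raise ValueError(
                f"{sid}: risk allele {risk!r} is neither {v.minor_allele!r} "
                f"nor {v.major_allele!r}"
            )
        if missing_policy == "mean_impute":
            c = np.where(np.isnan(c), np.nanmean(c), c)
        counts[:, j] = c
    prs = counts.sum(axis=1)
    table = pd.DataFrame({"prs": prs}, index=genotypes.subject_ids)
    table.index.name = "subject_id"
    table["category"] = pd.Series(
        [None if np.isnan(p) else categorize_prs(p) for p in prs],
        index=table.index, dtype=object,
    )
    return PrsProfile(table=table)


def categorize_prs(
    prs: float,
    cutoffs: tuple[int, int] = (3, 6),
) -> str:
    """Map a risk-allele count to Low/Medium/High.

    ``cutoffs = (low_max, high_min)``: Low is <= low_max, High is >=
    high_min, Medium is everything between — the default (3, 6) encodes the
    <=3 / 4-5 / >=6 rule.  The three ranges must partition the non-negative
    integers with a non-empty Medium band.
    """
    low_max, high_min = cutoffs
    if high_min <= low_max + 1:
        raise ValueError(
            f"cutoffs {cutoffs} leave no Medium band: need high_min > low_max + 1"
        )
    if prs < 0:
        raise ValueError("PRS cannot be negative")
    if prs <= low_max:
        return "Low"
    if prs < high_min:
        return "Medium"
    return "High"


def categorize_prs_series(
    prs: pd.Series,
    cutoffs: tuple[int, int] | None = (3, 6),
    mode: str = "fixed",
) -> pd.Series:
    """Vectorised categorisation; ``mode="tertile"`` uses empirical tertiles
    instead of fixed cutoffs."""
    if mode == "tertile":
        q1, q2 = prs.quantile([1 / 3, 2 / 3])
        out = pd.Series(
            np.where(prs <= q1, "Low", np.where(prs <= q2, "Medium", "High")),
            index=prs.index, dtype=object,
        )
        out[prs.isna()] = None
        return out
    return prs.map(lambda p: None if pd.isna(p) else categorize_prs(p, cutoffs))


def prs_association(
    categories: pd.Series,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict[str, AssocResult]:
    """Logistic regression of the outcome on PRS category dummies
    (Low = reference) plus covariates; Wald OR and 95% CI per category."""
    cat = pd.Series(categories).astype(object)
    y = np.asarray(outcome, dtype=float)
    keep = cat.notna().to_numpy()
    cat = cat[keep]
    y = y[keep]
    if (cat == "Low").sum() == 0:
        raise ValueError("Low-PRS reference category is empty")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    present = [c for c in ("Medium", "High") if (cat == c).any()]
    for c in ("Medium", "High"):
        if c not in present:
            warnings.warn(f"{c}-PRS category is empty; dropped from the model")
    dummies = np.column_stack([(cat == c).to_numpy(float) for c in present])
    design_cols = [np.ones(len(y)), *dummies.T]
    if covariates is not None:
        design_cols.extend(np.asarray(build_design(covariates))[keep].T)
    design = np.column_stack(design_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200, tol=1e-8)
    z = 1.959963984540054
    out = {}
    for i, c in enumerate(present, start=1):
        beta, se = fit.params[i], fit.bse[i]
        out[c] = AssocResult(
            variant_id=c, beta=float(beta), se=float(se),
            or_value=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p_adjusted_model=float(fit.pvalues[i]), n_used=len(y),
        )
    return out
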
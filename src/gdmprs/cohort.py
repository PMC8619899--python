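"""Cohort data model: variants, genotype dosage matrices and phenotype tables.

Conventions used throughout the package
---------------------------------------
* Positions are 1-based inclusive, as in PLINK ``.bim`` and VCF.
* Dosages count copies of the **minor** allele: values in {0, 1, 2} with
  ``numpy.nan`` for a missing call (never a -9 sentinel).
* After allele orientation is normalised the minor-allele frequency lies in
  [0, 0.5]; a risk allele used for polygenic scoring may still be the major
  allele and is mapped onto this orientation at scoring time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "derive_t2dm_status",
    "categorize_income",
    "EDUCATION_LEVELS",
    "INCOME_LEVELS",
    "SMOKING_LEVELS",
    "ALCOHOL_LEVELS",
]

#: Categorical level sets for the lifestyle questionnaire variables.
EDUCATION_LEVELS = ("<high school", "high school", ">=college")
INCOME_LEVELS = ("Low (<$2000)", "Medium ($2000-4000)", "High (>$4000)")
SMOKING_LEVELS = ("never", "past", "current")
ALCOHOL_LEVELS = ("none", "mild", "moderate")


@dataclass(frozen=True)
class VariantRecord:
    """A single SNP with its alleles oriented so that ``maf`` <= 0.5."""

    id: str
    chrom: str
    pos: int
    minor_allele: str
    major_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.minor_allele == self.major_allele:
            raise ValueError(
                f"{self.id}: minor and major allele are both {self.minor_allele!r}"
            )
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"{self.id}: MAF {self.maf} outside [0, 0.5]")


class GenotypeMatrix:
    """Subjects x variants minor-allele dosage matrix with variant metadata.

    Parameters
    ----------
    variants:
        Ordered variant metadata; order matches the columns of ``dosages``.
    dosages:
        Float array of shape (n_subjects, n_variants) with values in
        {0, 1, 2, nan}.
    subject_ids:
        Optional subject identifiers; defaults to ``S000001`` ...
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        dosages: np.ndarray,
        subject_ids: Sequence[str] | None = None,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional (subjects x variants)")
        if dosages.shape[1] != len(variants):
            raise ValueError(
                f"{dosages.shape[1]} dosage columns but {len(variants)} variants"
            )
        ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(dosages[~ok])
            raise ValueError(f"invalid dosage values {bad}; expected 0/1/2/nan")
        if subject_ids is None:
            subject_ids = [f"S{i + 1:06d}" for i in range(dosages.shape[0])]
        if len(subject_ids) != dosages.shape[0]:
            raise ValueError("subject_ids length does not match dosage rows")
        self.variants = list(variants)
        self.dosages = dosages
        self.subject_ids = list(subject_ids)
        self._index = {v.id: j for j, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate variant ids")

    # -- basic container protocol -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        return self.dosages[:, self._index[variant_id]]

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self._index[variant_id]]

    def subset(self, variant_ids: Iterable[str]) -> "GenotypeMatrix":
        """New matrix restricted to ``variant_ids`` (given order preserved)."""
        ids = list(variant_ids)
        cols = [self._index[i] for i in ids]
        return GenotypeMatrix(
            [self.variants[c] for c in cols],
            self.dosages[:, cols],
            self.subject_ids,
        )

    # -- summaries ---------------------------------------------------------------
    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def observed_maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def het_rate(self) -> np.ndarray:
        """Per-variant heterozygote fraction among non-missing calls."""
        ishet = self.dosages == 1.0
        nonmiss = ~np.isnan(self.dosages)
        with np.errstate(invalid="ignore"):
            return ishet.sum(axis=0) / nonmiss.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.subject_ids, columns=self.variant_ids
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_subjects} subjects x {self.n_variants} variants)"


def derive_t2dm_status(
    fasting_glucose: pd.Series,
    hba1c: pd.Series,
    hypoglycemic_agent: pd.Series | None = None,
) -> pd.Series:
    """Type 2 diabetes case definition for women enrolled after age 40.

    A subject is a T2DM case iff fasting serum glucose > 126 mg/dL, or
    HbA1c >= 6.5%, or she takes hypoglycemic agents.
    """
    status = (fasting_glucose > 126.0) | (hba1c >= 6.5)
    if hypoglycemic_agent is not None:
        status = status | hypoglycemic_agent.fillna(0).astype(bool)
    return status.astype(int)


def categorize_income(monthly_usd: float) -> str:
    """Map a monthly household income in USD onto the three survey levels."""
    if monthly_usd < 2000:
        return INCOME_LEVELS[0]
    if monthly_usd <= 4000:
        return INCOME_LEVELS[1]
    return INCOME_LEVELS[2]


@dataclass
class PhenotypeTable:
    """Per-subject outcomes, covariates and lifestyle variables.

    Wraps a :class:`pandas.DataFrame` indexed by subject id.  Canonical
    columns (all optional except the outcomes actually used downstream):

    ``gdm_status``, ``t2dm_status`` (0/1), ``fasting_glucose`` (mg/dL),
    ``hba1c`` (%), ``age``, ``age_first_pregnancy``, ``bmi_at_20`` (kg/m2),
    ``residence_area``, ``childbirth``, ``education``, ``income``,
    ``energy_intake`` (% of estimated requirement), ``alcohol``, ``smoking``,
    ``exercise``, ``breastfeeding_years`` and one score column per dietary
    pattern.
    """

    data: pd.DataFrame

    CATEGORICAL_LEVELS = {
        "education": EDUCATION_LEVELS,
        "income": INCOME_LEVELS,
        "smoking": SMOKING_LEVELS,
        "alcohol": ALCOHOL_LEVELS,
    }

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate subject ids in phenotype table")
        for col, levels in self.CATEGORICAL_LEVELS.items():
            if col in df.columns:
                vals = df[col].dropna()
                bad = ~vals.isin(levels)
                if bad.any():
                    rows = list(vals.index[bad][:10])
                    raise ValueError(
                        f"unknown {col} level(s) {sorted(vals[bad].unique())} "
                        f"in rows {rows}"
                    )
        if "breastfeeding_years" in df.columns:
            if (df["breastfeeding_years"].dropna() < 0).any():
                raise ValueError("negative breastfeeding_years")
        if {"gdm_status", "pre_pregnancy_diabetes"} <= set(df.columns):
            both = (df["gdm_status"] == 1) & (df["pre_pregnancy_diabetes"] == 1)
            if both.any():
                raise ValueError(
                    "subjects flagged both GDM-case and pre-pregnancy diabetic: "
                    f"{list(df.index[both][:10])}"
                )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def with_columns(self, **cols) -> "PhenotypeTable":
        return PhenotypeTable(self.data.assign(**cols))
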
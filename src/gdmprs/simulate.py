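"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, for a
women-only middle-aged cohort: Hardy-Weinberg genotypes at specified minor
allele frequencies with optional two-locus LD, a planted (possibly epistatic)
penetrance for gestational diabetes, covariate effects, a polygenic-score x
diet interaction on later-life type 2 diabetes, and latent-factor food
frequency intakes.

Planted effects are expressed on the logit scale.  Epistasis terms act on
*centered* dosage products, ``(g_i - 2 maf_i)(g_j - 2 maf_j)``, so that a
specification with zero main-effect logits produces marginally null single
SNP odds ratios while the joint two-locus penetrance still varies across
genotype cells — the "pure epistasis" regime that the GMDR search is designed
to detect.  Covariate effects are likewise applied to mean-centered covariate
values, so the baseline logit anchors the population prevalence.

All generators are pure functions of their inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    ALCOHOL_LEVELS,
    EDUCATION_LEVELS,
    INCOME_LEVELS,
    SMOKING_LEVELS,
    GenotypeMatrix,
    PhenotypeTable,
    VariantRecord,
)

__all__ = [
    "VariantSimSpec",
    "PenetranceSpec",
    "LifestyleEffectSpec",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_gdm",
    "simulate_t2dm",
    "simulate_ffq",
    "default_variant_panel",
    "default_penetrance",
    "simulate_cohort",
]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSimSpec:
    """One simulated variant: MAF plus an optional LD partner.

    ``ld_with`` names an *earlier* variant in the panel; ``ld_r2`` is the
    target squared allelic correlation with that partner, achieved at the
    haplotype level (positive D).
    """

    id: str
    maf: float
    chrom: str = "1"
    pos: int = 0
    minor_allele: str = "A"
    major_allele: str = "G"
    ld_with: str | None = None
    ld_r2: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(
                f"{self.id}: MAF must be in (0, 0.5], got {self.maf} "
                "(monomorphic variants are disallowed)"
            )
        if (self.ld_with is None) != (self.ld_r2 is None):
            raise ValueError(f"{self.id}: ld_with and ld_r2 must be given together")
        if self.ld_r2 is not None and not (0.0 <= self.ld_r2 <= 1.0):
            raise ValueError(f"{self.id}: ld_r2 must be in [0, 1]")


def _conditional_haplotype(rng, partner_hap: np.ndarray, p_a: float, p_b: float,
                           r2: float, vid: str) -> np.ndarray:
    """Draw minor-allele indicators for a new locus given partner haplotypes.

    Solves the two-locus haplotype frequency p_AB = p_a p_b + D with
    D = sqrt(r2 * p_a q_a p_b q_b), and rejects infeasible (MAF, r2) pairs.
    """
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    d = np.sqrt(r2 * p_a * q_a * p_b * q_b)
    d_max = min(p_a * q_b, q_a * p_b)
    if d > d_max + 1e-12:
        r2_max = d_max**2 / (p_a * q_a * p_b * q_b)
        raise ValueError(
            f"{vid}: target r2={r2} infeasible for MAFs ({p_a}, {p_b}); "
            f"maximum attainable r2 is {r2_max:.4f}"
        )
    p_ab = p_a * p_b + d
    p_b_given_a = p_ab / p_a
    p_b_given_not_a = (p_b - p_ab) / q_a
    u = rng.random(partner_hap.shape)
    return np.where(partner_hap == 1, u < p_b_given_a, u < p_b_given_not_a).astype(np.int8)


def simulate_genotypes(
    n_subjects: int,
    variant_specs: Sequence[VariantSimSpec],
    seed: int,
) -> GenotypeMatrix:
    """Draw HWE genotypes, honouring any requested two-locus LD.

    Independent variants are drawn as two Bernoulli(maf) haplotypes per
    subject (genotype frequencies p^2, 2pq, q^2); LD pairs are drawn at the
    haplotype level so the target r-squared holds in expectation.
    """
    rng = np.random.default_rng(seed)
    haplotypes: dict[str, np.ndarray] = {}
    dosages = np.empty((n_subjects, len(variant_specs)))
    variants = []
    for j, spec in enumerate(variant_specs):
        if spec.ld_with is None:
            hap = (rng.random((n_subjects, 2)) < spec.maf).astype(np.int8)
        else:
            if spec.ld_with not in haplotypes:
                raise ValueError(
                    f"{spec.id}: LD partner {spec.ld_with!r} must be an earlier variant"
                )
            partner = haplotypes[spec.ld_with]
            p_a = next(v.maf for v in variant_specs if v.id == spec.ld_with)
            hap = _conditional_haplotype(rng, partner, p_a, spec.maf, spec.ld_r2, spec.id)
        haplotypes[spec.id] = hap
        dosages[:, j] = hap.sum(axis=1)
        variants.append(
            VariantRecord(
                id=spec.id, chrom=spec.chrom,
                pos=spec.pos or (j + 1) * 1000,
                minor_allele=spec.minor_allele, major_allele=spec.major_allele,
                maf=spec.maf,
            )
        )
    return GenotypeMatrix(variants, dosages)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

#: Default parametric families for the questionnaire covariates.  Continuous
#: variables are normal (mean, sd, low, high); categorical variables carry the
#: level probabilities.  Values mirror a middle-aged women-only cohort.
DEFAULT_COVARIATE_FAMILIES: dict = {
    "age": {"mean": 53.0, "sd": 8.0, "low": 40.0, "high": 90.0},
    "age_first_pregnancy": {"mean": 25.2, "sd": 3.2, "low": 15.0, "high": 45.0},
    "bmi_at_20": {"mean": 20.3, "sd": 2.2, "low": 14.0, "high": 40.0},
    "energy_intake": {"mean": 99.0, "sd": 3.0, "low": 80.0, "high": 130.0},
    "residence_area": {"levels": ("urban", "rural"), "probs": (0.7, 0.3)},
    "childbirth": {"prob": 0.97},
    "education": {"levels": EDUCATION_LEVELS, "probs": (0.20, 0.23, 0.57)},
    "income": {"levels": INCOME_LEVELS, "probs": (0.11, 0.44, 0.45)},
    "alcohol": {"levels": ALCOHOL_LEVELS, "probs": (0.60, 0.30, 0.10)},
    "smoking": {"levels": SMOKING_LEVELS, "probs": (0.97, 0.02, 0.01)},
    "exercise": {"prob": 0.52},
    # ~14% never breastfed; durations among the rest exponential, mean 1.5 y
    "breastfeeding": {"prob_none": 0.136, "mean_years": 1.5},
}


def simulate_covariates(
    n_subjects: int,
    seed: int,
    families: Mapping[str, Mapping] | None = None,
) -> pd.DataFrame:
    """Draw the covariate/lifestyle table from simple parametric families."""
    fam = dict(DEFAULT_COVARIATE_FAMILIES)
    if families:
        fam.update(families)
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in ("age", "age_first_pregnancy", "bmi_at_20", "energy_intake"):
        f = fam[name]
        out[name] = np.clip(rng.normal(f["mean"], f["sd"], n_subjects),
                            f["low"], f["high"])
    for name in ("residence_area", "education", "income", "alcohol", "smoking"):
        f = fam[name]
        out[name] = rng.choice(f["levels"], size=n_subjects, p=f["probs"])
    for name in ("childbirth", "exercise"):
        out[name] = (rng.random(n_subjects) < fam[name]["prob"]).astype(int)
    bf = fam["breastfeeding"]
    none = rng.random(n_subjects) < bf["prob_none"]
    years = rng.exponential(bf["mean_years"], n_subjects)
    out["breastfeeding_years"] = np.where(none, 0.0, years)
    df = pd.DataFrame(out, index=[f"S{i + 1:06d}" for i in range(n_subjects)])
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

@dataclass
class PenetranceSpec:
    """Logit-scale penetrance for the GDM outcome.

    ``epistasis_terms`` are ``(snp_i, snp_j, logit)`` triples acting on
    centered dosage products; ``covariate_logits`` maps covariate column ->
    per-unit logit on the mean-centered covariate.
    """

    model_snps: list[str] = field(default_factory=list)
    baseline_logit: float = _logit(0.03)
    per_allele_logits: dict[str, float] = field(default_factory=dict)
    epistasis_terms: list[tuple[str, str, float]] = field(default_factory=list)
    covariate_logits: dict[str, float] = field(default_factory=dict)

    def validate(self, genotypes: GenotypeMatrix) -> None:
        known = set(genotypes.variant_ids)
        referenced = set(self.model_snps) | set(self.per_allele_logits)
        for a, b, _ in self.epistasis_terms:
            referenced |= {a, b}
        missing = referenced - known
        if missing:
            raise ValueError(f"penetrance references unknown SNPs {sorted(missing)}")


def _numeric_covariate(col: pd.Series) -> np.ndarray:
    if col.dtype == object:
        # categorical covariate: integer-code the levels for the planted effect
        return pd.Categorical(col).codes.astype(float)
    return col.to_numpy(dtype=float)


def simulate_gdm(
    genotypes: GenotypeMatrix,
    spec: PenetranceSpec,
    covariates: pd.DataFrame,
    seed: int,
) -> PhenotypeTable:
    """Draw GDM case/control status under a planted penetrance.

    P(GDM) = inverse-logit(baseline + per-allele terms + centered epistasis
    terms + centered covariate terms).
    """
    spec.validate(genotypes)
    if len(covariates) != genotypes.n_subjects:
        raise ValueError("covariate table and genotype matrix differ in size")
    rng = np.random.default_rng(seed)
    eta = np.full(genotypes.n_subjects, spec.baseline_logit)
    for snp, beta in spec.per_allele_logits.items():
        eta += beta * np.nan_to_num(genotypes.column(snp))
    for snp_i, snp_j, beta in spec.epistasis_terms:
        ci = genotypes.column(snp_i) - 2.0 * genotypes.variant(snp_i).maf
        cj = genotypes.column(snp_j) - 2.0 * genotypes.variant(snp_j).maf
        eta += beta * np.nan_to_num(ci * cj)
    for cov, beta in spec.covariate_logits.items():
        x = _numeric_covariate(covariates[cov])
        eta += beta * (x - x.mean())
    prob = _invlogit(eta)
    if not ((prob > 0.0) & (prob < 1.0)).all():
        raise ValueError("penetrance produced degenerate probabilities")
    gdm = (rng.random(len(prob)) < prob).astype(int)
    df = covariates.copy()
    df.index = genotypes.subject_ids
    df.index.name = "subject_id"
    df["gdm_status"] = gdm
    return PhenotypeTable(df)


@dataclass
class LifestyleEffectSpec:
    """Logit-scale effects for the later-life T2DM outcome."""

    baseline_logit: float = _logit(0.076)
    prs_logit_per_allele: float = 0.0
    diet_main_logit: float = 0.0
    prs_by_diet_logit: float = 0.0
    breastfeeding_logit: float = 0.0

    def validate(self) -> None:
        for name in ("baseline_logit", "prs_logit_per_allele", "diet_main_logit",
                     "prs_by_diet_logit", "breastfeeding_logit"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def simulate_t2dm(
    prs: np.ndarray | pd.Series,
    lifestyle: pd.DataFrame,
    spec: LifestyleEffectSpec,
    seed: int,
) -> np.ndarray:
    """Draw T2DM status from PRS, diet and breastfeeding effects.

    ``lifestyle`` must hold a binary ``diet_high`` column and
    ``breastfeeding_years``; breastfeeding enters as the >= 1 year indicator.
    The PRS and the PRS x diet product are mean-centered so the baseline
    logit anchors prevalence.
    """
    spec.validate()
    prs = np.asarray(prs, dtype=float)
    if len(prs) != len(lifestyle):
        raise ValueError("prs and lifestyle tables are not aligned")
    rng = np.random.default_rng(seed)
    diet_high = lifestyle["diet_high"].to_numpy(dtype=float)
    bf_long = (lifestyle["breastfeeding_years"].to_numpy(dtype=float) >= 1.0)
    prs_c = prs - prs.mean()
    inter = prs_c * diet_high
    eta = (
        spec.baseline_logit
        + spec.prs_logit_per_allele * prs_c
        + spec.diet_main_logit * (diet_high - diet_high.mean())
        + spec.prs_by_diet_logit * (inter - inter.mean())
        + spec.breastfeeding_logit * (bf_long - bf_long.mean())
    )
    return (rng.random(len(eta)) < _invlogit(eta)).astype(int)


# ---------------------------------------------------------------------------
# Food-frequency intakes
# ---------------------------------------------------------------------------

def simulate_ffq(
    n_subjects: int,
    n_groups: int = 29,
    factor_loadings: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Latent-factor food-group intakes: loadings @ factors + noise.

    Latent factors are standard normal; columns are shifted to be
    non-negative (intakes are amounts).  ``factor_loadings`` has shape
    (n_groups, n_factors); ``None`` means pure noise.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, (n_subjects, n_groups))
    if factor_loadings is not None:
        loadings = np.asarray(factor_loadings, dtype=float)
        if not np.isfinite(loadings).all():
            raise ValueError("factor loadings must be finite")
        if loadings.shape[0] != n_groups:
            raise ValueError("loadings rows must equal n_groups")
        factors = rng.normal(size=(n_subjects, loadings.shape[1]))
        x = x + factors @ loadings.T
    x -= np.minimum(x.min(axis=0), 0.0)  # shift to non-negative
    cols = [f"group{g + 1:02d}" for g in range(n_groups)]
    df = pd.DataFrame(x, columns=cols,
                      index=[f"S{i + 1:06d}" for i in range(n_subjects)])
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# Default study-shaped cohort
# ---------------------------------------------------------------------------

#: Ten-SNP candidate panel with the chromosomes, positions and minor-allele
#: frequencies of the gestational-diabetes candidate set this pipeline was
#: built around.
TABLE_PANEL: list[tuple[str, str, int, str, str, float]] = [
    ("rs6821589", "4", 89192792, "G", "A", 0.011),
    ("rs189428800", "4", 123779401, "A", "G", 0.015),
    ("rs7754840", "6", 20661250, "C", "G", 0.476),
    ("rs181540079", "7", 17370229, "C", "T", 0.015),
    ("rs11975504", "7", 151481965, "C", "T", 0.051),
    ("rs916855529", "9", 8721355, "G", "A", 0.397),
    ("rs2274034", "10", 6019248, "C", "T", 0.419),
    ("rs148031082", "12", 80309656, "A", "G", 0.014),
    ("rs9589710", "13", 93967361, "T", "C", 0.364),
    ("rs80164908", "18", 7862077, "G", "A", 0.158),
]

#: SNPs of the 5-SNP best interaction model used for default PRS planting.
BEST_MODEL_SNPS = ["rs916855529", "rs9589710", "rs7754840", "rs11975504", "rs80164908"]

#: Default planted epistasis strength (logit per centered-dosage product),
#: chosen so the GMDR search detects the pair with near-certain power in a
#: cohort of 10,000 subjects at ~3% prevalence.
DEFAULT_EPISTASIS_LOGIT = 2.0


def default_variant_panel() -> list[VariantSimSpec]:
    return [
        VariantSimSpec(id=vid, chrom=chrom, pos=pos,
                       minor_allele=mi, major_allele=ma, maf=maf)
        for vid, chrom, pos, mi, ma, maf in TABLE_PANEL
    ]


def default_penetrance() -> PenetranceSpec:
    """Default GDM penetrance: per-allele effects on the five best-model
    SNPs, a planted epistatic pair, and positive age-at-first-pregnancy and
    BMI-at-20 covariate effects.

    Effects are scaled for a 10,000-subject cohort at ~3% prevalence: the
    rarer SNPs carry larger logits so every planted SNP is individually
    discoverable at the genome-wide candidate threshold (p < 1e-4), the
    scaled-down analogue of a much larger discovery cohort.
    """
    per_allele = {
        "rs916855529": np.log(1.5),
        "rs9589710": np.log(1.5),
        "rs7754840": np.log(1.45),
        "rs11975504": np.log(2.2),   # MAF 0.051
        "rs80164908": np.log(1.8),   # MAF 0.158
    }
    return PenetranceSpec(
        model_snps=list(BEST_MODEL_SNPS),
        baseline_logit=_logit(0.03),
        per_allele_logits=per_allele,
        epistasis_terms=[("rs916855529", "rs9589710", DEFAULT_EPISTASIS_LOGIT)],
        covariate_logits={"age_first_pregnancy": 0.05, "bmi_at_20": 0.15},
    )


def simulate_cohort(
    n_subjects: int = 10_000,
    seed: int = 0,
    penetrance: PenetranceSpec | None = None,
    lifestyle_spec: LifestyleEffectSpec | None = None,
    variant_specs: Sequence[VariantSimSpec] | None = None,
) -> dict:
    """Generate a full synthetic cohort bundle.

    Returns a dict with ``genotypes`` (GenotypeMatrix), ``phenotypes``
    (PhenotypeTable with gdm_status and t2dm_status) and ``ffq`` (intake
    table).  T2DM is planted on the true risk-allele count over the
    penetrance's model SNPs interacting with the first dietary pattern.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    specs = list(variant_specs) if variant_specs is not None else default_variant_panel()
    pen = penetrance if penetrance is not None else default_penetrance()
    life = lifestyle_spec if lifestyle_spec is not None else LifestyleEffectSpec(
        prs_logit_per_allele=0.0, diet_main_logit=-0.2,
        prs_by_diet_logit=np.log(1.15), breastfeeding_logit=np.log(0.887),
    )
    genotypes = simulate_genotypes(n_subjects, specs, int(seeds[0]))
    covariates = simulate_covariates(n_subjects, int(seeds[1]))
    phenotypes = simulate_gdm(genotypes, pen, covariates, int(seeds[2]))

    # three planted orthogonal dietary factors, ~10 salient groups each
    loadings = np.zeros((29, 3))
    loadings[0:10, 0] = 1.0
    loadings[10:20, 1] = 1.0
    loadings[20:29, 2] = 1.0
    ffq = simulate_ffq(n_subjects, 29, loadings, noise_sd=1.0, seed=int(seeds[3]))
    ffq.index = genotypes.subject_ids

    # true risk-allele burden over the planted model SNPs (minor = risk here)
    true_prs = sum(np.nan_to_num(genotypes.column(s)) for s in pen.model_snps)
    pattern1 = ffq.iloc[:, 0:10].sum(axis=1)
    diet_high = (pattern1 >= pattern1.quantile(0.7)).astype(int)
    lifestyle = pd.DataFrame(
        {"diet_high": diet_high.to_numpy(),
         "breastfeeding_years": phenotypes.data["breastfeeding_years"].to_numpy()},
        index=genotypes.subject_ids,
    )
    t2dm = simulate_t2dm(true_prs, lifestyle, life, int(seeds[4]))
    df = phenotypes.data.copy()
    df["t2dm_status"] = t2dm
    # continuous glycemic traits tied to T2DM status plus noise
    glucose_rng = np.random.default_rng(int(seeds[4]) + 1)
    df["fasting_glucose"] = np.clip(
        glucose_rng.normal(91.0 + 25.0 * t2dm + 1.2 * (true_prs - true_prs.mean()), 9.0),
        60.0, 300.0,
    )
    df["hba1c"] = np.clip(
        glucose_rng.normal(5.6 + 1.3 * t2dm + 0.05 * (true_prs - true_prs.mean()), 0.35),
        4.0, 14.0,
    )
    return {
        "genotypes": genotypes,
        "phenotypes": PhenotypeTable(df),
        "ffq": ffq,
        "true_model_snps": list(pen.model_snps),
        "true_epistasis_pairs": [(a, b) for a, b, _ in pen.epistasis_terms],
    }
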
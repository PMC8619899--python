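# Methods

## Cohort data model

Genotypes are held as a subjects × variants dosage matrix counting copies of
the **minor** allele (0/1/2, `NaN` for a missing call — never a sentinel
value). Positions are 1-based, as in PLINK `.bim` and VCF. On read, alleles
are re-oriented so the stored minor-allele frequency is ≤ 0.5; a risk allele
used for scoring may still be the major allele and is mapped onto this
orientation at scoring time. Phenotypes are a per-subject table of outcomes
(GDM status; T2DM status, derivable as fasting glucose > 126 mg/dL, HbA1c
≥ 6.5% or hypoglycemic medication), covariates (age, age at first
pregnancy, BMI at age 20 kg/m², residence area, childbirth, education and
income at three levels, energy intake as % of estimated requirement,
alcohol, smoking, exercise, breastfeeding years) and per-pattern diet
scores.

## Quality control

Per variant: missing-call rate < 4%, heterozygote fraction, and
Hardy-Weinberg equilibrium p > 0.05. HWE uses the 1-df chi-square
goodness-of-fit test against (p², 2pq, q²) when every expected genotype
count is ≥ 5, otherwise the conditional exact test (sum of probabilities of
heterozygote counts no more probable than observed, allele counts fixed);
both are exposed directly. A monomorphic variant is defined to have p = 1
and is flagged.

The heterozygosity criterion deserves a note. As a *variant-level* rule,
"het < 30%" rejects every common SNP, since HWE heterozygosity is 2pq —
up to 0.5 at MAF 0.5. The criterion is meaningful chip-wide as a
*per-sample* screen. `apply_qc_filters` therefore defaults to the strict
variant-level reading (threshold 0.30) for callers who want it, while the
pipeline's default config sets the variant-level threshold to 0.55, just
above the HWE maximum, where it acts purely as a heterozygote-excess
(genotyping-artifact) guard; per-sample heterozygosity, genotyping accuracy
and sex checks are treated as upstream chip-level guarantees.

## Association and LD pruning

Single-SNP association is an additive (allele-dosage) logistic regression
with configurable covariates (default: age at first pregnancy, BMI at age
20, residence area, childbirth experience, education), fitted by
maximum likelihood with Wald 95% CIs `exp(β ± 1.96·SE)`. Subjects missing a
variant's dosage are dropped from that variant's fit; complete separation
is flagged (infinite CI) rather than raised. Candidates are variants with
adjusted p strictly below 1e-4, sorted ascending.

LD r² between two variants is D²/(p_A q_A p_B q_B) with haplotype
frequencies estimated by EM from the 3×3 unphased genotype table (only the
double heterozygote has ambiguous phase). Pruning greedily scans the
candidates in (p, position) order and keeps a variant iff its r² with every
kept variant **on the same chromosome** is ≤ 0.3; cross-chromosome pairs
are never tested. A configurable top-N cap (default 10) stands in for the
annotation-based shortlisting step that cannot be automated offline.

## GMDR

The score residual is s_i = y_i − p̂_i from the covariate-only logistic
null model (with an intercept, residuals sum to zero; with no covariates,
s_i = y_i − ȳ). For a k-SNP subset each subject maps to one of 3ᵏ
multilocus cells (subjects missing any subset genotype are excluded); a
cell is high-risk iff its summed *training* scores exceed a threshold
(default 0). Ties at the threshold and cells unseen in training are
low-risk — a deterministic, conservative rule. Balanced accuracy is
½(sensitivity + specificity) of the induced high/low classification against
the observed outcome.

Cross-validation uses a seeded, case/control-stratified 10-fold partition
(unstratified folds can produce single-class test sets at a few-percent
prevalence). For each subset size k, every subset is evaluated in every
fold; the subset with the highest training balanced accuracy wins the fold,
and the reported best-of-size-k is the subset winning most folds (ties:
higher mean TEBA, then lexicographic SNP ids). CVC is the number of folds
won; TRBA/TEBA are across-fold means for the winning subset; the sign
statistic counts folds whose test balanced accuracy exceeds 0.5 (ties count
as failures), with p the one-sided Binomial(n_folds, ½) upper tail. This
operationalisation reproduces the standard 10-fold printed pairs
4→0.828, 6→0.377, 8→0.055, 9→0.011, 10→0.001 at 3-decimal rounding.

Selection optimism. The across-fold-mean TEBA of the *selected* subset is
not an unbiased estimate of chance performance under the null: selecting
among C(10,2) = 45 subsets by training accuracy inflates it by roughly
σ·E[max of correlated deviates], where σ is the standard deviation of
whole-cohort chance balanced accuracy (≈ 0.017 with 300 cases). At 3%
prevalence and n = 10,000 the measured mean null TEBA is ≈ 0.536, not 0.50;
the classic fold-winner estimator (selection independent of the evaluation
fold) is unbiased at 0.500, and a balanced-prevalence null gives ≈ 0.51.
Users comparing a fitted TEBA against 0.5 should rely on the sign test and
CVC, not the raw TEBA, exactly because of this optimism.

The search is exhaustive by design; candidate sets are capped at ~10-20
SNPs, so no heuristic search is needed.

## Polygenic risk score

The PRS is the unweighted sum of risk-allele counts over the best model's
SNPs (a 5-SNP model gives 0–10). The risk allele per SNP is the allele with
OR > 1 in the candidate association (recorded for audit). Missing model
genotypes either void the subject's score (default) or are mean-imputed
(sensitivity analysis, documented as non-integer). Categories default to
the fixed cutoffs Low ≤ 3, Medium 4–5, High ≥ 6, which presuppose the
0–10 range of a 5-SNP model; for other model sizes the pipeline falls back
to empirical tertiles (a fixed-cutoff override is available). Association
with outcomes uses category dummies (Low = reference) plus one of four
named covariate presets — the two written "model 1/2" definitions and the
two alternative listings used for the odds-ratio figure; both pairs ship
because the source descriptions differ, selected by config key.

## Interaction analysis

Stratified odds ratios are independent per-stratum logistic fits with a
common covariate set. The interaction p-value for binary outcomes comes
from a likelihood-ratio test of the product term(s) between the PRS
(numeric or category dummies) and the stratifier, with Wald as an option;
for continuous glycemic traits it is the extra-sum-of-squares F-test in a
two-way ANCOVA. Adjusted group means are least-squares means at covariate
grand means, compared pairwise via the studentized-range (Tukey HSD)
distribution. Lifestyle dichotomisations: breastfeeding at ≥ 1 year, diet
scores at the 70th percentile. No multiple-testing correction is applied
across the lifestyle panel by default (per-test α = 0.05); Bonferroni is
available and off by default.

## Dietary patterns

Item intakes are summed into 29 predefined food groups (the item→group
mapping is an editable config). Patterns are principal components of the
*standardized* group intakes — intake scales differ by orders of magnitude,
so the eigenvalue rule is only meaningful on the correlation matrix.
Components with eigenvalue > 1.5 are retained (fixed-k override available),
varimax-rotated with Kaiser normalization, and sign-fixed so each
component's dominant group loads positively. Subject scores use the
regression method (R⁻¹·Λ on standardized intakes), standardized to unit
variance. Groups with |rotated loading| ≥ 0.40 label a pattern; subjects at
or above the 70th percentile of a score (linear-interpolation quantile,
ties to the high side) form its high-intake group. Pattern names (e.g.
Korean-style balanced diet) are user labels in config, never inferred.

## Synthetic cohort

The generator reproduces the statistical structure the analysis assumes,
not any real LD or allele-frequency spectrum:

- **Genotypes**: two Bernoulli(MAF) haplotypes per subject (HWE by
  construction); an LD pair is drawn at the haplotype level from
  frequencies solved from (MAF_A, MAF_B, r²), with infeasible combinations
  rejected. The default 10-SNP panel uses the chromosomes, positions and
  MAFs of the candidate set the pipeline was built around.
- **GDM**: P = inverse-logit of baseline + per-allele terms + epistasis +
  covariate terms. Epistasis acts on centered dosage products
  (g_i − 2·MAF_i)(g_j − 2·MAF_j), so zero main-effect logits give
  near-null marginal odds ratios while the joint penetrance varies across
  cells. The logistic link leaks a small marginal effect at strong
  interactions (OR ≈ 1.1–1.2 at logit 2.0) via genotype-dependent spread
  plus convexity; at the default strength this stays far below the
  candidate-selection threshold, so detection is genuinely joint.
  Covariates enter mean-centered, so the baseline logit anchors prevalence
  (default 3%).
- **Defaults**: 10,000 subjects; ~3% GDM and ~7.6% baseline T2DM;
  per-allele logits of log 1.45–log 2.2 on the five model SNPs (rarer SNPs
  carry larger logits so each is discoverable at p < 1e-4 at this reduced
  cohort size — the scaled-down analogue of a several-fold larger discovery
  cohort); epistasis logit 2.0 between the two common model SNPs, at which
  the GMDR search recovers the pair with essentially full power; a modest
  PRS × diet interaction (log 1.15 per allele in the high-diet group) and a
  protective breastfeeding effect (log 0.887) on T2DM; normal/categorical
  covariate families with survey-like frequencies (all configurable).
- **Food intakes**: loadings · standard-normal latent factors + Gaussian
  noise, shifted non-negative; the default plants three orthogonal
  block-structured factors.

What passing tests on this cohort do **not** show: robustness to real
LD structure, population stratification, genotyping batch effects,
questionnaire measurement error, or case-control ascertainment — none of
which the generator emulates.

## Numerical choices

- Logistic fits: statsmodels maximum likelihood, convergence tolerance
  1e-8; aliased covariate columns are dropped (never the intercept or the
  term of interest); separation is flagged, not raised.
- EM for haplotype frequencies: tolerance 1e-10, ≤ 1000 iterations; r²
  clipped to [0, 1].
- Varimax: SVD-form iteration, tolerance 1e-12; rotation matrices are
  orthonormal, preserving communalities to 1e-8.
- Exact HWE ties: outcomes with probability within a 1e-12 relative band
  of the observed outcome count as "no more probable".
- Quantiles: linear interpolation between order statistics throughout.
- All stochastic components take explicit integer seeds; fixed seed ⇒
  byte-identical pipeline outputs.

## Problem sizes

Validation experiments run at the reduced scale the package adopts as its
testing conditions: cohorts of 10,000 subjects (50,000–200,000 where a
convergence claim needs it), 10-SNP panels, 10-fold cross-validation,
100–1,000 replicates for coverage/calibration claims. These sizes make the
whole suite reproducible on a laptop while keeping every statistical claim
at the stated tolerance.

## Known limitations

- No population-structure correction or mixed models; no imputation.
- The narrowing of genome-wide candidates by functional annotation is
  represented only by a top-N cap.
- The PRS is unweighted by design; no effect-size-weighted variant.
- The selected-model TEBA carries selection optimism (see above); inference
  should use the sign test and CVC.
- Tukey HSD p-values assume homoscedastic normal errors of the ANCOVA.
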
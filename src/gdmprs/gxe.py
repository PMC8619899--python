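"""PRS x environment interaction analysis.

Provides the stratified odds-ratio tables (PRS category vs outcome within
levels of a lifestyle stratifier), interaction-term tests (logistic
likelihood-ratio test for binary outcomes, ANCOVA F-test for continuous
glycemic traits), covariate-adjusted group means with Tukey HSD multiple
comparisons, and the crude chi-square / one-way ANOVA descriptive tests.

Lifestyle dichotomisations follow the cohort conventions: breastfeeding at
>= 1 year, dietary-pattern scores at their 70th percentile, PRS collapsed to
its three categories (product terms act on the category dummies).  No
multiple-testing correction is applied across the lifestyle panel by
default; Bonferroni is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .prs import prs_association
from .qc import AssocResult, build_design

__all__ = [
    "InteractionResult",
    "stratified_association",
    "interaction_test",
    "adjusted_group_means",
    "crude_group_tests",
    "interaction_report",
]


@dataclass
class InteractionResult:
    """Stratified ORs plus the PRS x stratifier interaction p-value."""

    stratifier: str
    per_stratum: dict[object, dict[str, AssocResult]]
    interaction_p: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum, ors in self.per_stratum.items():
            row: dict[str, object] = {"stratifier": self.stratifier, "stratum": stratum,
                                      "Low": "1 (ref)"}
            for cat in ("Medium", "High"):
                r = ors.get(cat)
                row[cat] = (
                    f"{r.or_value:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})"
                    if r is not None else "NA"
                )
            rows.append(row)
        df = pd.DataFrame(rows)
        df["interaction_p"] = self.interaction_p
        return df


def stratified_association(
    categories: pd.Series,
    outcome: np.ndarray | pd.Series,
    stratifier: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict[object, dict[str, AssocResult]]:
    """Independent PRS-category logistic fits within each stratifier level.

    A degenerate stratum (single outcome class or empty Low reference)
    yields an empty OR dict with a warning rather than an error.
    """
    strat = pd.Series(np.asarray(stratifier), index=pd.Series(categories).index)
    out: dict[object, dict[str, AssocResult]] = {}
    for level in sorted(strat.dropna().unique(), key=str):
        mask = (strat == level).to_numpy()
        cats = pd.Series(categories)[mask]
        y = np.asarray(outcome)[mask]
        cov = covariates.iloc[mask] if covariates is not None else None
        try:
            out[level] = prs_association(cats, y, cov)
        except ValueError as exc:
            warnings.warn(f"stratum {level!r} degenerate: {exc}")
            out[level] = {}
    return out


def _interaction_design(
    main_a: pd.Series | np.ndarray,
    main_b: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None,
):
    """Build (reduced, full) design matrices: mains (+covariates) without and
    with the product terms.  Categorical mains are dummy-coded."""

    def encode(x):
        arr = np.asarray(x)
        if arr.dtype.kind not in "OUS":
            return arr.astype(float).reshape(-1, 1)
        s = pd.Series(arr, dtype=object)
        levels = sorted(s.dropna().unique(), key=str)
        if "Low" in levels:  # PRS categories: keep Low as reference
            levels = ["Low"] + [l for l in levels if l != "Low"]
        return np.column_stack([(s == l).to_numpy(float) for l in levels[1:]])

    a = encode(main_a)
    b = encode(main_b)
    n = a.shape[0]
    cols = [np.ones(n), *a.T, *b.T]
    if covariates is not None:
        cols.extend(np.asarray(build_design(covariates), dtype=float).T)
    reduced = np.column_stack(cols)
    products = [ac * bc for ac in a.T for bc in b.T]
    full = np.column_stack([reduced, *[p.reshape(-1, 1) for p in products]])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            "interaction columns are collinear with the main effects/covariates"
        )
    return reduced, full, len(products)


def interaction_test(
    outcome: np.ndarray | pd.Series,
    prs_term: pd.Series | np.ndarray,
    stratifier: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    outcome_type: str = "binary",
    method: str = "lrt",
) -> float:
    """P-value of the PRS x stratifier interaction term.

    Binary outcomes: logistic model with both main effects, covariates and
    the product term(s); likelihood-ratio test by default (``method="wald"``
    for the Wald test).  Continuous outcomes: two-way ANCOVA, extra-sum-of-
    squares F-test of the interaction block.
    """
    y = np.asarray(outcome, dtype=float)
    reduced, full, n_inter = _interaction_design(prs_term, stratifier, covariates)
    if outcome_type == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_full = sm.Logit(y, full).fit(disp=0, maxiter=200, tol=1e-8)
            if method == "wald":
                contrast = np.zeros((n_inter, full.shape[1]))
                for i in range(n_inter):
                    contrast[i, full.shape[1] - n_inter + i] = 1.0
                return float(fit_full.wald_test(contrast, scalar=True).pvalue)
            fit_red = sm.Logit(y, reduced).fit(disp=0, maxiter=200, tol=1e-8)
        lr = 2.0 * (fit_full.llf - fit_red.llf)
        return float(stats.chi2.sf(max(lr, 0.0), df=n_inter))
    if outcome_type == "continuous":
        fit_full = sm.OLS(y, full).fit()
        fit_red = sm.OLS(y, reduced).fit()
        df_resid = fit_full.df_resid
        f = ((fit_red.ssr - fit_full.ssr) / n_inter) / (fit_full.ssr / df_resid)
        return float(stats.f.sf(f, n_inter, df_resid))
    raise ValueError(f"unknown outcome type {outcome_type!r}")


@dataclass
class AdjustedMeans:
    """Least-squares group means at covariate grand means, with Tukey HSD."""

    means: pd.Series
    se: pd.Series
    tukey: pd.DataFrame  # columns: group1, group2, diff, q, p


def adjusted_group_means(
    outcome: np.ndarray | pd.Series,
    groups: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> AdjustedMeans:
    """ANCOVA-adjusted means per group and Tukey HSD pairwise p-values.

    Fits ``y ~ group dummies + covariates`` by OLS, evaluates each group's
    prediction at the covariate grand means, and compares groups with the
    studentized-range distribution.  Groups with fewer than 2 subjects are
    excluded with a warning.
    """
    y = np.asarray(outcome, dtype=float)
    g = pd.Series(np.asarray(groups, dtype=object))
    sizes = g.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"groups {small} have < 2 subjects; excluded")
    keep = ~g.isin(small).to_numpy()
    y, g = y[keep], g[keep].reset_index(drop=True)
    levels = sorted(g.unique(), key=str)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    dummies = np.column_stack([(g == l).to_numpy(float) for l in levels[1:]])
    cols = [np.ones(len(y)), *dummies.T]
    cov = None
    if covariates is not None:
        cov = np.asarray(build_design(covariates), dtype=float)[keep]
        cols.extend(cov.T)
    design = np.column_stack(cols)
    fit = sm.OLS(y, design).fit()

    k = len(levels)
    grand = cov.mean(axis=0) if cov is not None else np.empty(0)
    means, ses, vectors = {}, {}, {}
    for i, level in enumerate(levels):
        vec = np.zeros(design.shape[1])
        vec[0] = 1.0
        if i > 0:
            vec[i] = 1.0
        vec[k:] = grand
        means[level] = float(vec @ fit.params)
        ses[level] = float(np.sqrt(vec @ fit.cov_params() @ vec))
        vectors[level] = vec

    rows = []
    df_resid = fit.df_resid
    for i in range(k):
        for j in range(i + 1, k):
            diff_vec = vectors[levels[i]] - vectors[levels[j]]
            diff = float(diff_vec @ fit.params)
            se_diff = float(np.sqrt(diff_vec @ fit.cov_params() @ diff_vec))
            q = abs(diff) / se_diff * np.sqrt(2.0) if se_diff > 0 else 0.0
            p = float(stats.studentized_range.sf(q, k, df_resid)) if q > 0 else 1.0
            rows.append(dict(group1=levels[i], group2=levels[j],
                             diff=diff, q=q, p=min(p, 1.0)))
    return AdjustedMeans(
        means=pd.Series(means), se=pd.Series(ses), tukey=pd.DataFrame(rows)
    )


def crude_group_tests(
    data: pd.DataFrame | pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray | None = None,
    kind: str = "auto",
) -> float:
    """Descriptive-table tests: Pearson chi-square for a contingency table,
    one-way ANOVA for continuous values by group.

    Pass either a pre-tabulated contingency ``DataFrame`` (rows x columns of
    counts) or raw values plus ``groups``.
    """
    if isinstance(data, pd.DataFrame) and groups is None:
        table = data.to_numpy(dtype=float)
        if min(table.shape) < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        stat, p, _, expected = stats.chi2_contingency(table, correction=False)
        if (expected <= 0).any():
            raise ValueError("chi-square requires positive expected counts")
        return float(p)
    values = np.asarray(data, dtype=float)
    g = pd.Series(np.asarray(groups, dtype=object))
    if kind == "auto":
        kind = "anova"
    if kind == "anova":
        samples = [values[(g == l).to_numpy()] for l in g.unique()]
        if len(samples) < 2:
            raise ValueError("ANOVA needs at least two groups")
        return float(stats.f_oneway(*samples).pvalue)
    if kind == "chi2":
        table = pd.crosstab(g, pd.Series(data)).to_numpy(dtype=float)
        if min(table.shape) < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        return float(stats.chi2_contingency(table, correction=False)[1])
    raise ValueError(f"unknown test kind {kind!r}")


def interaction_report(
    categories: pd.Series,
    outcome: np.ndarray | pd.Series,
    stratifiers: dict[str, pd.Series | np.ndarray],
    covariates: pd.DataFrame | None = None,
    bonferroni: bool = False,
) -> list[InteractionResult]:
    """Per-lifestyle interaction rows: stratified ORs + interaction p.

    ``bonferroni=True`` multiplies each interaction p by the number of
    stratifiers tested (off by default, matching a per-test alpha of 0.05).
    """
    results = []
    m = len(stratifiers)
    for name, strat in stratifiers.items():
        per_stratum = stratified_association(categories, outcome, strat, covariates)
        p = interaction_test(outcome, categories, strat, covariates, "binary")
        if bonferroni:
            p = min(1.0, p * m)
        results.append(InteractionResult(name, per_stratum, p))
    return results
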
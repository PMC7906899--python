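"""Inferential layer: nested linear models, genetics utilities, calibration.

The analysis tests associations between BMI, two obesity-related
polymorphisms (an FTO variant coded 0/1/2 risk alleles and the Taq1A
variant near DRD2 coded carrier / non-carrier), and normalized reward
network metrics, via F-tests comparing full against null ordinary
least-squares models:

* Model 1:  metric ~ age + sex + BMI            (null: age + sex)
* Model 2:  Model 1 + head motion (ln FD) + smoking + depression
            (ln CES-D + 1) + education
* Model 3:  BMI ~ age + sex + FTO * Taq1A       (null: Model 4)
* Model 4:  BMI ~ age + sex + FTO + Taq1A
* Model 5:  metric ~ age + sex + FTO * Taq1A    (null: Model 6)
* Model 6:  metric ~ age + sex + FTO + Taq1A    (null: age + sex)

Family-wise error is controlled by Bonferroni: alpha = 0.05/4 = 0.0125
across the four network metrics and 0.05/10 = 0.005 across the ten
node-wise tests.  Sensitivity reruns exclude moderate BMI outliers
(above Q3 + 1.5 IQR); exploratory comparisons add sex x BMI and
age x BMI interactions.

Genetics utilities: minor allele frequency, Hardy-Weinberg chi-square,
risk-allele grouping, and the power of the two-sided two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from patsy import dmatrices

__all__ = [
    "ModelComparisonResult",
    "HierarchyResults",
    "compare_nested",
    "run_model_hierarchy",
    "minor_allele_frequency",
    "hwe_chi2",
    "genotype_groups",
    "power_two_sample",
    "bonferroni",
    "bmi_outlier_mask",
    "simulate_null_rejection_rate",
    "simulate_ci_coverage",
    "simulate_recovery",
]

ALPHA_NETWORK = 0.0125   # 0.05 / 4 network metrics
ALPHA_NODE = 0.005       # 0.05 / 10 reward nodes
NETWORK_METRICS = ("fa_cs", "fa_cc", "nos_cs", "nos_cc")


# ---------------------------------------------------------------------------
# Nested model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparisonResult:
    full_formula: str
    null_formula: str
    focal_term: str | None
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p_focal: float | None     # two-sided t-test of the focal coefficient
    adj_r2: float             # of the full model
    method: str               # "F" or "LRT"
    stat: float               # F or LRT chi-square
    df_num: int
    df_den: int | None        # None for LRT
    comparison_p: float
    n: int


def _fit_pair(data: pd.DataFrame, full: str, null: str):
    """OLS fits of both models on the listwise-complete subset of the full
    model (the null's variables are a subset, so the rows coincide)."""
    y1, x1 = dmatrices(full, data, return_type="dataframe")
    sub = data.loc[x1.index]
    y0, x0 = dmatrices(null, sub, return_type="dataframe")
    if len(x0) != len(x1):
        raise ValueError("null model drops rows the full model keeps: not nested")
    extra = set(x0.columns) - set(x1.columns)
    if extra:
        raise ValueError(f"models are not nested; null-only terms: {sorted(extra)}")
    n, p1 = x1.shape
    if n <= p1:
        raise ValueError(f"n = {n} observations cannot identify {p1} parameters")
    rank = np.linalg.matrix_rank(x1.to_numpy())
    if rank < p1:
        _, r = np.linalg.qr(x1.to_numpy())
        aliased = [c for c, d in zip(x1.columns, np.abs(np.diag(r)))
                   if d < 1e-8 * max(np.abs(np.diag(r)))]
        raise ValueError(f"collinear design; aliased terms: {aliased}")
    fit1 = sm.OLS(y1.iloc[:, 0], x1).fit()
    fit0 = sm.OLS(y0.iloc[:, 0], x0).fit()
    return fit1, fit0, x1, x0


def compare_nested(data: pd.DataFrame, full: str, null: str,
                   focal: str | None = None,
                   method: str = "F") -> ModelComparisonResult:
    """Compare a full against a nested null OLS model.

    ``method="F"`` uses F = ((RSS0 - RSS1)/d) / (RSS1/(n - p1));
    ``method="LRT"`` uses twice the Gaussian log-likelihood difference
    against chi-square(d).  The focal coefficient (by design-column name;
    auto-detected when the full model adds exactly one column) is reported
    with its estimate, normal-theory 95% CI and two-sided p.  Categorical
    predictors are treatment-coded against the lowest level.
    """
    if method not in ("F", "LRT"):
        raise ValueError("method must be 'F' or 'LRT'")
    fit1, fit0, x1, x0 = _fit_pair(data, full, null)
    added = [c for c in x1.columns if c not in set(x0.columns)]
    if not added:
        raise ValueError("full model adds no terms over the null")
    if focal is None and len(added) == 1:
        focal = added[0]

    n, p1 = x1.shape
    d = len(added)
    rss1, rss0 = float(fit1.ssr), float(fit0.ssr)
    if method == "F":
        denom = rss1 / (n - p1)
        stat = ((rss0 - rss1) / d) / denom if denom > 0 else np.inf
        comparison_p = float(sps.f.sf(stat, d, n - p1)) if np.isfinite(stat) else 0.0
        df_den = n - p1
    else:
        stat = 2.0 * (float(fit1.llf) - float(fit0.llf))
        comparison_p = float(sps.chi2.sf(stat, d))
        df_den = None

    estimate = ci_low = ci_high = p_focal = None
    if focal is not None:
        if focal not in x1.columns:
            raise KeyError(f"focal term {focal!r} not in the full design "
                           f"({list(x1.columns)})")
        estimate = float(fit1.params[focal])
        ci = fit1.conf_int().loc[focal]
        ci_low, ci_high = float(ci[0]), float(ci[1])
        p_focal = float(fit1.pvalues[focal])

    return ModelComparisonResult(
        full_formula=full, null_formula=null, focal_term=focal,
        estimate=estimate, ci_low=ci_low, ci_high=ci_high, p_focal=p_focal,
        adj_r2=float(fit1.rsquared_adj), method=method, stat=float(stat),
        df_num=d, df_den=df_den, comparison_p=comparison_p, n=n,
    )


# ---------------------------------------------------------------------------
# Model hierarchy
# ---------------------------------------------------------------------------

BASE_NULL = "age + C(sex)"
CONFOUNDERS = "ln_mean_fd + C(smoking) + ln_cesd + C(education)"


@dataclass
class HierarchyResults:
    results: pd.DataFrame
    alpha_network: float = ALPHA_NETWORK
    alpha_node: float = ALPHA_NODE


def _row(family: str, outcome: str, term: str, res: ModelComparisonResult,
         alpha: float | None = None, **extra) -> dict:
    return {"family": family, "outcome": outcome, "term": term,
            "estimate": res.estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p_focal, "adj_r2": res.adj_r2,
            "method": res.method, "comparison_stat": res.stat,
            "comparison_p": res.comparison_p, "n": res.n, "alpha": alpha,
            **extra}


def _coef_rows(family: str, outcome: str, fit_res: ModelComparisonResult,
               data: pd.DataFrame, full: str, null: str, terms: list,
               alpha: float | None) -> list:
    """Rows for several coefficients of one fitted full model."""
    rows = []
    for term in terms:
        r = compare_nested(data, full, null, focal=term,
                           method=fit_res.method)
        rows.append(_row(family, outcome, term, r, alpha))
    return rows


def bmi_outlier_mask(bmi, k: float = 1.5) -> np.ndarray:
    """True for moderate upper outliers: BMI > Q3 + k*IQR (linear-
    interpolated quartiles)."""
    v = np.asarray(bmi, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    return v > q3 + k * (q3 - q1)


def run_model_hierarchy(cohort: pd.DataFrame, alpha: float = 0.05,
                        metrics=NETWORK_METRICS,
                        sensitivity: bool = True,
                        exploratory: bool = True) -> HierarchyResults:
    """The full inferential cascade on a participant table.

    Requires the demographic/genetic columns plus the four network metrics;
    node-wise columns (``fa_cs_*`` / ``nos_cs_*``) are picked up when
    present.  ln-transformed FD and CES-D columns are derived on the fly
    if absent.
    """
    from .qc import log_transform_covariates

    df = cohort.copy()
    if "ln_mean_fd" not in df or "ln_cesd" not in df:
        df = log_transform_covariates(df)

    alpha_network = bonferroni(alpha, len(metrics))
    alpha_node = bonferroni(alpha, 10)
    rows: list[dict] = []

    # --- Model 1: metric ~ age + sex + BMI, per network metric ------------
    model1: dict[str, ModelComparisonResult] = {}
    for metric in metrics:
        res = compare_nested(df, f"{metric} ~ {BASE_NULL} + bmi", f"{metric} ~ {BASE_NULL}",
                             focal="bmi")
        model1[metric] = res
        rows.append(_row("model1", metric, "bmi", res, alpha_network))

    # --- Model 2: confounder-adjusted, for Bonferroni-significant metrics -
    for metric in metrics:
        if model1[metric].comparison_p < alpha_network:
            res = compare_nested(
                df, f"{metric} ~ {BASE_NULL} + {CONFOUNDERS} + bmi",
                f"{metric} ~ {BASE_NULL} + {CONFOUNDERS}", focal="bmi")
            rows.append(_row("model2", metric, "bmi", res, alpha))

    # --- Node-wise Model 2 for edge types with network-wide significance --
    for edge in ("fa", "nos"):
        edge_sig = any(model1[m].comparison_p < alpha
                       for m in metrics if m.startswith(edge))
        node_cols = [c for c in df.columns if c.startswith(f"{edge}_cs_")]
        if not edge_sig or not node_cols:
            continue
        for col in node_cols:
            res = compare_nested(
                df, f"Q('{col}') ~ {BASE_NULL} + {CONFOUNDERS} + bmi",
                f"Q('{col}') ~ {BASE_NULL} + {CONFOUNDERS}", focal="bmi")
            rows.append(_row("model2_nodewise", col, "bmi", res, alpha_node))

    # --- Models 3 vs 4: genotype interaction on BMI -----------------------
    m3 = f"bmi ~ {BASE_NULL} + C(fto) * taq1a"
    m4 = f"bmi ~ {BASE_NULL} + C(fto) + taq1a"
    res_f = compare_nested(df, m3, m4, method="F")
    rows.append(_row("model3_vs_4", "bmi", "C(fto):taq1a", res_f, alpha))
    res_chi = compare_nested(df, m3, m4, method="LRT")
    rows.append(_row("model3_vs_4", "bmi", "C(fto):taq1a", res_chi, alpha))

    # --- Model 4 main genetic effects on BMI ------------------------------
    res4 = compare_nested(df, m4, f"bmi ~ {BASE_NULL}")
    rows.append(_row("model4", "bmi", "FTO+Taq1A", res4, alpha))
    rows += _coef_rows("model4_terms", "bmi", res4, df, m4, f"bmi ~ {BASE_NULL}",
                       ["C(fto)[T.1]", "C(fto)[T.2]", "taq1a"], alpha)

    # --- Models 5 vs 6 and genotype main effects per metric ---------------
    for metric in metrics:
        m5 = f"{metric} ~ {BASE_NULL} + C(fto) * taq1a"
        m6 = f"{metric} ~ {BASE_NULL} + C(fto) + taq1a"
        res5 = compare_nested(df, m5, m6, method="F")
        rows.append(_row("model5_vs_6", metric, "C(fto):taq1a", res5, alpha))
        res6 = compare_nested(df, m6, f"{metric} ~ {BASE_NULL}")
        rows.append(_row("model6", metric, "FTO+Taq1A", res6, alpha))
        for term in ["C(fto)[T.1]", "C(fto)[T.2]", "taq1a"]:
            r = compare_nested(df, m6, f"{metric} ~ {BASE_NULL}", focal=term)
            rows.append(_row("model6_terms", metric, term, r, alpha))
            # additionally adjusted for BMI
            r_adj = compare_nested(df, f"{m6} + bmi",
                                   f"{metric} ~ {BASE_NULL} + bmi", focal=term)
            rows.append(_row("model6_terms_bmi_adj", metric, term, r_adj, alpha))

    # --- Sensitivity: exclude moderate BMI outliers -----------------------
    if sensitivity:
        keep = ~bmi_outlier_mask(df["bmi"].to_numpy(), k=1.5)
        sub = df.loc[keep]
        for metric in metrics:
            res = compare_nested(sub, f"{metric} ~ {BASE_NULL} + bmi",
                                 f"{metric} ~ {BASE_NULL}", focal="bmi")
            rows.append(_row("model1_bmi_sensitivity", metric, "bmi", res,
                             alpha_network, n_excluded=int((~keep).sum())))

    # --- Exploratory: sex x BMI and age x BMI on network strength --------
    if exploratory:
        for metric in [m for m in metrics if m.endswith("_cs")]:
            base = f"{metric} ~ {BASE_NULL} + bmi"
            for inter in ("C(sex):bmi", "age:bmi"):
                res = compare_nested(df, f"{base} + {inter}", base, method="F")
                rows.append(_row("exploratory_interaction", metric, inter,
                                 res, alpha))

    return HierarchyResults(pd.DataFrame(rows), alpha_network, alpha_node)


# ---------------------------------------------------------------------------
# Genetics utilities
# ---------------------------------------------------------------------------

def minor_allele_frequency(genotype_counts) -> float:
    """MAF from (n_homRef, n_het, n_homAlt): the alternate-allele
    frequency (n_het + 2 n_homAlt) / (2 n), folded to [0, 0.5]."""
    aa, ab, bb = (int(x) for x in genotype_counts)
    if min(aa, ab, bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = aa + ab + bb
    if n == 0:
        raise ValueError("no genotypes")
    freq = (ab + 2 * bb) / (2 * n)
    return min(freq, 1.0 - freq)


def hwe_chi2(genotype_counts) -> tuple[float, float]:
    """Pearson chi-square test (df = 1, no continuity correction) of
    Hardy-Weinberg proportions, with expected counts (n p^2, 2 n p q,
    n q^2) from the observed allele frequency."""
    aa, ab, bb = (int(x) for x in genotype_counts)
    n = aa + ab + bb
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * aa + ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p**2, 2 * n * p * q, n * q**2])
    if (expected == 0).any():
        raise ValueError("an expected genotype count is zero (monomorphic locus)")
    observed = np.array([aa, ab, bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, 1))


def genotype_groups(genotypes: pd.Series, locus: str) -> pd.Series:
    """Risk-allele grouping from genotype strings.

    FTO: TT -> 0, AT -> 1, AA -> 2 (additive risk-allele count).
    Taq1A: TT -> 0, AT/AA -> 1 (carrier of at least one risk allele).
    """
    g = genotypes.str.upper().str.replace("TA", "AT", regex=False)
    if locus.lower() == "fto":
        mapping = {"TT": 0, "AT": 1, "AA": 2}
    elif locus.lower() == "taq1a":
        mapping = {"TT": 0, "AT": 1, "AA": 1}
    else:
        raise ValueError("locus must be 'fto' or 'taq1a'")
    out = g.map(mapping)
    if out.isna().any() and not genotypes.isna().all():
        bad = sorted(set(g[out.isna()].dropna()))
        if bad:
            raise ValueError(f"unrecognized genotypes: {bad}")
    return out


def power_two_sample(n1: int, n2: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at Cohen's d with unequal
    group sizes: noncentrality delta = d / sqrt(1/n1 + 1/n2),
    df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    delta = d / np.sqrt(1.0 / n1 + 1.0 / n2)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta))


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test level alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Calibration simulations (type-I error, CI coverage, parameter recovery)
# ---------------------------------------------------------------------------

def _null_cohort_spec(n: int, seed: int):
    from .synthetic import CohortSpec

    return CohortSpec(n=n, fto_bmi_effect=0.0, taq1a_bmi_effect=0.0,
                      beta_bmi_on_metric={m: 0.0 for m in NETWORK_METRICS},
                      covariate_effects={}, include_nodewise=False, seed=seed)


def simulate_null_rejection_rate(n: int = 347, reps: int = 1000,
                                 alpha: float = 0.05, seed: int = 0,
                                 metric: str = "nos_cs"):
    """Type-I error of the Model-1 comparison under a cohort with no
    planted effects.  Returns (rejection rate, p-value array)."""
    from .synthetic import make_cohort

    rng = np.random.default_rng(seed)
    pvals = np.empty(reps)
    for i in range(reps):
        df = make_cohort(_null_cohort_spec(n, int(rng.integers(2**31 - 1))))
        res = compare_nested(df, f"{metric} ~ {BASE_NULL} + bmi",
                             f"{metric} ~ {BASE_NULL}", focal="bmi")
        pvals[i] = res.comparison_p
    return float((pvals < alpha).mean()), pvals


def simulate_ci_coverage(beta: float = -0.0025, n: int = 347,
                         reps: int = 2000, seed: int = 0,
                         metric: str = "nos_cs"):
    """Fraction of 95% CIs for the planted BMI coefficient that cover it."""
    from .synthetic import CohortSpec, make_cohort

    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(reps):
        spec = CohortSpec(n=n, beta_bmi_on_metric={metric: beta},
                          covariate_effects={}, include_nodewise=False,
                          seed=int(rng.integers(2**31 - 1)))
        df = make_cohort(spec)
        res = compare_nested(df, f"{metric} ~ {BASE_NULL} + bmi",
                             f"{metric} ~ {BASE_NULL}", focal="bmi")
        covered += int(res.ci_low <= beta <= res.ci_high)
    return covered / reps


def simulate_recovery(beta: float = -0.0025, n: int = 347, reps: int = 500,
                      seed: int = 0, metric: str = "nos_cs"):
    """Mean estimate, Monte-Carlo standard error, and mean CI half-width
    of the refitted planted coefficient."""
    from .synthetic import CohortSpec, make_cohort

    rng = np.random.default_rng(seed)
    est = np.empty(reps)
    halfwidth = np.empty(reps)
    for i in range(reps):
        spec = CohortSpec(n=n, beta_bmi_on_metric={metric: beta},
                          covariate_effects={}, include_nodewise=False,
                          seed=int(rng.integers(2**31 - 1)))
        df = make_cohort(spec)
        res = compare_nested(df, f"{metric} ~ {BASE_NULL} + bmi",
                             f"{metric} ~ {BASE_NULL}", focal="bmi")
        est[i] = res.estimate
        halfwidth[i] = (res.ci_high - res.ci_low) / 2.0
    return {
        "mean_estimate": float(est.mean()),
        "mc_se": float(est.std(ddof=1) / np.sqrt(reps)),
        "mean_ci_halfwidth": float(halfwidth.mean()),
    }
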
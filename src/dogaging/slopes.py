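"""Rate-of-decline comparison: group x age interaction models around the breakpoint.

For each grouping variable the data are split at each group's own breakpoint,
the before-breakpoint parts merged into one dataset and the after parts into
another, and each dataset is modelled as

    trait ~ group + age + group:age

If residual normality (skew/kurtosis bounds) and Levene's homogeneity hold,
classical covariance and an F-type interaction test are used; otherwise a
heteroscedasticity-consistent (HC3) sandwich covariance with a Wald chi2
test.  Significant interactions are followed by Bonferroni-corrected
pairwise slope contrasts with partial eta squared (classical) or
exponentiated slope differences (robust) as effect sizes.  A breed
random-intercept replication (REML) checks robustness to uneven breed
representation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "SlopeModelResult",
    "PairwiseContrast",
    "split_at_breakpoint",
    "levene_test",
    "fit_slope_model",
    "pairwise_slope_contrasts",
    "fit_random_intercept_model",
]

SKEW_BOUND = 1.0
EXCESS_KURTOSIS_BOUND = 2.0


def split_at_breakpoint(
    data: pd.DataFrame, breakpoints: dict, group_col: str, age_col: str = "age_years",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide each group at its own breakpoint; boundary dogs go 'before'."""
    groups = data[group_col].dropna().unique()
    missing = [g for g in groups if g not in breakpoints]
    if missing:
        raise KeyError(f"no breakpoint for group(s): {missing}")
    psi = data[group_col].map(breakpoints)
    age = pd.to_numeric(data[age_col], errors="coerce")
    keep = psi.notna() & age.notna()
    before = data.loc[keep & (age <= psi)]
    after = data.loc[keep & (age > psi)]
    return before, after


def levene_test(values, groups) -> tuple[float, float]:
    """Classic Levene test (absolute deviations from group means)."""
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    samples = [v[g == lev].to_numpy() for lev in g.dropna().unique()]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two observations")
    w, p = stats.levene(*samples, center="mean")
    return float(w), float(p)


@dataclass
class SlopeModelResult:
    """A fitted group x age model with its assumption report."""

    phase: str                   # "before" | "after"
    grouping: str
    groups: list
    coef_table: pd.DataFrame
    cov_type: str                # "classical" | "robust-sandwich"
    interaction_stat: float
    interaction_df: tuple
    interaction_p: float
    stat_name: str               # "F" | "Wald chi2"
    normality_ok: bool
    skew: float
    excess_kurtosis: float
    levene_w: float
    levene_p: float
    n: int
    dropped_groups: list = field(default_factory=list)
    fit: object = None           # statsmodels results (not serialized)
    random_intercept_var: float | None = None
    converged: bool = True


def _slope_vector(fit, group: str, groups: list, age_col: str) -> np.ndarray:
    """Contrast vector selecting the age slope of ``group``."""
    names = list(fit.model.exog_names)
    c = np.zeros(len(names))
    c[names.index(age_col)] = 1.0
    inter = f"C(grp, Treatment('{groups[0]}'))[T.{group}]:{age_col}"
    if inter in names:
        c[names.index(inter)] = 1.0
    return c


def fit_slope_model(
    data: pd.DataFrame, trait_col: str, group_col: str,
    age_col: str = "age_years", phase: str = "", robust: bool | None = None,
) -> SlopeModelResult:
    """Least squares trait ~ group*age with assumption-driven covariance choice.

    ``robust=None`` decides from the assumption checks; True/False forces.
    Groups with fewer than 3 observations are dropped with a warning flag.
    """
    df = data[[trait_col, group_col, age_col]].dropna().copy()
    df.columns = ["y", "grp", "age"]
    df["grp"] = df["grp"].astype(str)
    counts = df["grp"].value_counts()
    dropped = [g for g in counts.index if counts[g] < 3]
    if dropped:
        df = df[~df["grp"].isin(dropped)]
    groups = sorted(df["grp"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups with data")

    formula = f"y ~ C(grp, Treatment('{groups[0]}')) * age"
    base = smf.ols(formula, data=df).fit()

    resid = base.resid
    skew = float(stats.skew(resid))
    exk = float(stats.kurtosis(resid))
    normality_ok = abs(skew) < SKEW_BOUND and abs(exk) < EXCESS_KURTOSIS_BOUND
    lev_w, lev_p = levene_test(df["y"], df["grp"])
    assumptions_ok = normality_ok and lev_p > 0.05
    use_robust = (not assumptions_ok) if robust is None else bool(robust)

    fit = base.get_robustcov_results(cov_type="HC3") if use_robust else base

    inter_names = [n for n in base.model.exog_names if ":age" in n]
    K = np.zeros((len(inter_names), len(base.model.exog_names)))
    for i, nm in enumerate(inter_names):
        K[i, base.model.exog_names.index(nm)] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_robust:
            wt = fit.wald_test(K, scalar=True, use_f=False)
            stat, pval = float(wt.statistic), float(wt.pvalue)
            df_stat = (len(inter_names),)
            stat_name = "Wald chi2"
        else:
            wt = fit.wald_test(K, scalar=True, use_f=True)
            stat, pval = float(wt.statistic), float(wt.pvalue)
            df_stat = (len(inter_names), int(fit.df_resid))
            stat_name = "F"

    coef = pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "stat": fit.tvalues, "p": fit.pvalues,
    }, index=base.model.exog_names)

    return SlopeModelResult(
        phase=phase, grouping=group_col, groups=groups, coef_table=coef,
        cov_type="robust-sandwich" if use_robust else "classical",
        interaction_stat=stat, interaction_df=df_stat, interaction_p=pval,
        stat_name=stat_name, normality_ok=normality_ok, skew=skew,
        excess_kurtosis=exk, levene_w=lev_w, levene_p=lev_p, n=len(df),
        dropped_groups=dropped, fit=fit,
    )


@dataclass
class PairwiseContrast:
    group_a: str
    group_b: str
    slope_a: float
    slope_b: float
    difference: float       # slope_a - slope_b
    se: float
    p_raw: float
    p_adjusted: float       # Bonferroni: min(1, m * p_raw)
    effect_size: float
    effect_name: str        # "partial_eta2" | "exp_b"


def pairwise_slope_contrasts(result: SlopeModelResult) -> list:
    """All pairwise age-slope differences with Bonferroni adjustment."""
    fit = result.fit
    groups = result.groups
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    robust = result.cov_type == "robust-sandwich"
    params = np.asarray(fit.params)
    cov = np.asarray(fit.cov_params())
    dfr = int(fit.df_resid)
    out = []
    for a, b in pairs:
        ca = _slope_vector(fit, a, groups, "age")
        cb = _slope_vector(fit, b, groups, "age")
        c = ca - cb
        est = float(c @ params)
        se = float(np.sqrt(max(c @ cov @ c, 1e-300)))
        tval = est / se
        if robust:
            p_raw = 2.0 * stats.norm.sf(abs(tval))
            effect, ename = float(np.exp(est)), "exp_b"
        else:
            p_raw = 2.0 * stats.t.sf(abs(tval), dfr)
            effect = float(tval**2 / (tval**2 + dfr))   # partial eta2, 1-df contrast
            ename = "partial_eta2"
        out.append(PairwiseContrast(
            group_a=a, group_b=b,
            slope_a=float(ca @ params), slope_b=float(cb @ params),
            difference=est, se=se, p_raw=float(p_raw),
            p_adjusted=float(min(1.0, m * p_raw)),
            effect_size=effect, effect_name=ename,
        ))
    return out


def fit_random_intercept_model(
    data: pd.DataFrame, trait_col: str, group_col: str, breed_col: str = "breed",
    age_col: str = "age_years", phase: str = "",
) -> SlopeModelResult:
    """Same fixed effects plus a breed random intercept, fitted by REML."""
    df = data[[trait_col, group_col, age_col, breed_col]].dropna().copy()
    df.columns = ["y", "grp", "age", "breed"]
    df["grp"] = df["grp"].astype(str)
    if df["breed"].nunique() < 5:
        raise ValueError("need at least five breeds for the random-intercept model")
    groups = sorted(df["grp"].unique())
    formula = f"y ~ C(grp, Treatment('{groups[0]}')) * age"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["breed"])
        try:
            fit = model.fit(reml=True)
            converged = bool(getattr(fit, "converged", True))
        except Exception:
            fit = None
            converged = False
    if fit is None:
        res = fit_slope_model(df.rename(columns={"y": trait_col, "grp": group_col,
                                                 "age": age_col}),
                              trait_col, group_col, age_col, phase=phase)
        res.converged = False
        return res

    exog_names = list(fit.model.exog_names)
    inter_names = [n for n in exog_names if ":age" in n]
    K = np.zeros((len(inter_names), len(fit.params)))
    for i, nm in enumerate(inter_names):
        K[i, exog_names.index(nm)] = 1.0
    fe = np.asarray(fit.fe_params)
    covfe = np.asarray(fit.cov_params())[:len(fe), :len(fe)]
    Kfe = K[:, :len(fe)]
    est = Kfe @ fe
    covc = Kfe @ covfe @ Kfe.T
    wald = float(est @ np.linalg.pinv(covc) @ est)
    pval = float(stats.chi2.sf(wald, len(inter_names)))

    coef = pd.DataFrame({
        "coef": fe, "se": np.sqrt(np.diag(covfe)),
    }, index=exog_names[:len(fe)])
    lev_w, lev_p = levene_test(df["y"], df["grp"])
    return SlopeModelResult(
        phase=phase, grouping=group_col, groups=groups, coef_table=coef,
        cov_type="classical", interaction_stat=wald,
        interaction_df=(len(inter_names),), interaction_p=pval,
        stat_name="Wald chi2", normality_ok=True, skew=np.nan,
        excess_kurtosis=np.nan, levene_w=lev_w, levene_p=lev_p, n=len(df),
        fit=fit, random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        converged=converged,
    )
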
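"""Broken-line (segmented) regression: breakpoint estimation and testing.

The age-trajectory model is continuous piecewise-linear:

    E[y | x] = b0 + b1*x + sum_k delta_k * (x - psi_k)_+

with unknown breakpoints psi_k.  Estimation uses iterative linearization: at
the current psi the model is refit with an added "gap" regressor
-1{x > psi}, whose coefficient gamma measures the discontinuity the working
model would need; the update psi <- psi + gamma/delta drives gamma to zero.
At convergence SE(psi_hat) = SE(gamma)/|delta| (delta method), giving Wald
confidence intervals.

Breakpoint existence is tested with a Davies-type supremum test: the slope
change statistic is evaluated on a grid of candidate locations and the
p-value for the maximum is bounded using the total variation of the
statistic process.  Breakpoint-count selection runs these tests sequentially
(none vs >= 1, then 1 vs 2 on the one-breakpoint fit) with Bonferroni
correction across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PolyFitReport",
    "SegmentedFit",
    "BreakpointSelection",
    "fit_age_polynomials",
    "screen_trait",
    "davies_test",
    "fit_segmented",
    "select_breakpoints",
    "breakpoint_confint",
    "segment_slopes",
    "compare_breakpoints",
]


# ---------------------------------------------------------------------------
# Step 2: polynomial screening


@dataclass
class PolyFitReport:
    """R2/F/p for linear, quadratic, and cubic age regressions."""

    n: int
    r2: dict            # degree -> R2
    fstat: dict
    df: dict            # degree -> (df_model, df_resid)
    pvalues: dict
    constant_response: bool = False

    @property
    def max_r2(self) -> float:
        return max(self.r2.values())


def fit_age_polynomials(age, y) -> PolyFitReport:
    """OLS fits of y on age, age^2, age^3; R2, F and p per degree."""
    x = np.asarray(age, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(x)
    if n <= 4:
        raise ValueError("need more than 4 observations")
    tss = np.sum((yv - yv.mean()) ** 2)
    report = PolyFitReport(n=n, r2={}, fstat={}, df={}, pvalues={})
    if tss == 0:
        report.constant_response = True
        for d in (1, 2, 3):
            report.r2[d] = 0.0
            report.fstat[d] = 0.0
            report.df[d] = (d, n - d - 1)
            report.pvalues[d] = 1.0
        return report
    for d in (1, 2, 3):
        X = np.vander(x, d + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        rss = np.sum((yv - X @ beta) ** 2)
        r2 = 1.0 - rss / tss
        dfm, dfr = d, n - d - 1
        f = (r2 / dfm) / ((1.0 - r2) / dfr) if r2 < 1.0 else np.inf
        report.r2[d] = float(r2)
        report.fstat[d] = float(f)
        report.df[d] = (dfm, dfr)
        report.pvalues[d] = float(stats.f.sf(f, dfm, dfr)) if np.isfinite(f) else 0.0
    return report


def screen_trait(report: PolyFitReport, threshold: float = 0.1) -> str:
    """'drop' iff the best of the three R2 values is strictly below threshold."""
    return "drop" if report.max_r2 < threshold else "keep"


# ---------------------------------------------------------------------------
# Davies-type supremum test


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """OLS fit returning (beta, covariance, rss, df_resid)."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dfr = n - k
    XtX_inv = np.linalg.pinv(X.T @ X)
    sigma2 = rss / max(dfr, 1)
    return beta, sigma2 * XtX_inv, rss, dfr


def davies_test(
    age, y, base_design: np.ndarray | None = None, k: int = 10,
    trim: float = 0.05,
) -> float:
    """Davies-bound p-value for a slope change at an unknown location.

    Evaluates the t statistic of an added hinge (x - psi)_+ at ``k``
    equally spaced interior quantiles of age (outer ``trim`` fraction
    excluded) over the base design (default: intercept + age) and bounds the
    two-sided p-value of the supremum by

        p <= 2*(1 - Phi(M)) + V * exp(-M^2/2) / sqrt(8*pi)

    where V is the total variation of the signed statistic process.  With a
    single candidate the bound reduces to the plain two-sided p.
    """
    x = np.asarray(age, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(np.unique(x)) <= 2:
        raise ValueError("age must take more than two distinct values")
    if base_design is None:
        base_design = np.column_stack([np.ones_like(x), x])
    qs = np.linspace(trim, 1.0 - trim, k)
    candidates = np.unique(np.quantile(x, qs))
    tstats = []
    for psi in candidates:
        hinge = np.maximum(0.0, x - psi)
        if hinge.std() == 0 or (x <= psi).sum() < 3 or (x > psi).sum() < 3:
            continue
        X = np.column_stack([base_design, hinge])
        beta, cov, _, dfr = _ols(X, yv)
        se = np.sqrt(max(cov[-1, -1], 1e-300))
        tstats.append(beta[-1] / se)
    if not tstats:
        raise ValueError("no admissible candidate breakpoints")
    s = np.asarray(tstats)
    M = float(np.abs(s).max())
    V = float(np.abs(np.diff(s)).sum())
    p = 2.0 * stats.norm.sf(M) + V * np.exp(-0.5 * M**2) / np.sqrt(8.0 * np.pi)
    return float(min(1.0, max(p, 0.0)))


# ---------------------------------------------------------------------------
# Segmented fitting (iterative linearization)


@dataclass
class SegmentedFit:
    """A fitted broken-line model."""

    psi: np.ndarray               # breakpoint estimates (years)
    psi_se: np.ndarray
    intercept: float
    slopes: np.ndarray            # per-segment slopes (len = n_breakpoints + 1)
    slope_se: np.ndarray
    delta: np.ndarray             # slope changes at each breakpoint
    rss: float
    sigma2: float
    n: int
    x_range: tuple
    converged: bool
    flags: list = field(default_factory=list)
    cov_full: np.ndarray | None = None   # covariance of (b0, b1, deltas, gammas)

    @property
    def n_breakpoints(self) -> int:
        return len(self.psi)


def _segmented_design(x: np.ndarray, psi: np.ndarray, gaps: bool) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.maximum(0.0, x - p))
    if gaps:
        for p in psi:
            cols.append(-(x > p).astype(float))
    return np.column_stack(cols)


def _fit_once(
    x: np.ndarray, y: np.ndarray, psi0: np.ndarray,
    max_iter: int = 60, tol_t: float = 0.01, tol_psi: float = 1e-4,
) -> SegmentedFit | None:
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    psi = np.sort(np.asarray(psi0, dtype=float))
    nb = len(psi)
    flags: list = []
    converged = False

    def profile_rss(p: np.ndarray) -> float:
        X = _segmented_design(x, p, gaps=False)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    cur_rss = profile_rss(psi)
    eps = 0.02 * span
    for _ in range(max_iter):
        X = _segmented_design(x, psi, gaps=True)
        beta, cov, _, dfr = _ols(X, y)
        delta = beta[2:2 + nb]
        gamma = beta[2 + nb:2 + 2 * nb]
        if np.any(np.abs(delta) < 1e-12):
            return None
        step = gamma / delta
        # step-halving: the profile RSS must not increase (the raw update can
        # oscillate when the optimum sits at a data-point kink of the profile)
        new_psi, new_rss = psi, cur_rss
        h = 1.0
        for _half in range(12):
            trial = np.sort(np.clip(psi + h * step, lo + eps, hi - eps))
            if nb == 2 and trial[1] - trial[0] < eps:
                h *= 0.5
                continue
            trial_rss = profile_rss(trial)
            if trial_rss <= cur_rss + 1e-12:
                new_psi, new_rss = trial, trial_rss
                break
            h *= 0.5
        gamma_t = np.abs(gamma) / np.sqrt(np.maximum(np.diag(cov)[2 + nb:], 1e-300))
        moved = np.max(np.abs(new_psi - psi))
        psi, cur_rss = new_psi, new_rss
        if np.all(gamma_t < tol_t) or moved < tol_psi:
            converged = True
            break
    if not converged:
        flags.append("not converged")
    if nb == 2 and psi[1] - psi[0] < eps:
        flags.append("breakpoints collapsed")
        return None

    # final working fit with gap terms for SE(psi); final model without gaps
    Xg = _segmented_design(x, psi, gaps=True)
    beta_g, cov_g, _, _ = _ols(Xg, y)
    delta = beta_g[2:2 + nb]
    gamma_se = np.sqrt(np.maximum(np.diag(cov_g)[2 + nb:], 0.0))
    psi_se = gamma_se / np.maximum(np.abs(delta), 1e-12)

    X = _segmented_design(x, psi, gaps=False)
    beta, cov, rss, dfr = _ols(X, y)
    delta = beta[2:2 + nb]
    slopes = beta[1] + np.concatenate([[0.0], np.cumsum(delta)])
    slope_se = np.empty(nb + 1)
    for seg in range(nb + 1):
        c = np.zeros(len(beta))
        c[1] = 1.0
        c[2:2 + seg] = 1.0
        slope_se[seg] = float(np.sqrt(max(c @ cov @ c, 0.0)))
    if np.any(np.abs(psi - np.array([lo, hi])[None].T).min(axis=0) <= 0.021 * span):
        flags.append("breakpoint at boundary")
    return SegmentedFit(
        psi=psi, psi_se=psi_se, intercept=float(beta[0]), slopes=slopes,
        slope_se=slope_se, delta=delta, rss=rss, sigma2=rss / max(dfr, 1),
        n=len(x), x_range=(lo, hi), converged=converged, flags=flags,
        cov_full=cov_g,
    )


def fit_segmented(
    age, y, n_breakpoints: int = 1, psi0=None, n_restarts: int = 5,
    restart_seed: int = 12345,
) -> SegmentedFit:
    """Fit a broken-line model with 1 or 2 breakpoints.

    Default initialization: the median age (one breakpoint) or the 33rd/66th
    percentiles (two); ``n_restarts`` jittered restarts are run and the best
    RSS solution kept.
    """
    if n_breakpoints not in (1, 2):
        raise ValueError("n_breakpoints must be 1 or 2")
    x = np.asarray(age, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(yv)
    x, yv = x[ok], yv[ok]
    if len(np.unique(x)) <= n_breakpoints + 2:
        raise ValueError("too few distinct ages for a segmented fit")
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    if psi0 is None:
        psi0 = (np.quantile(x, [0.5]) if n_breakpoints == 1
                else np.quantile(x, [1 / 3, 2 / 3]))
    psi0 = np.atleast_1d(np.asarray(psi0, dtype=float))
    if np.any((psi0 <= lo) | (psi0 >= hi)):
        raise ValueError("initial breakpoints must lie inside the age range")

    rng = np.random.default_rng(restart_seed)
    starts = [psi0]
    for _ in range(n_restarts):
        jitter = rng.uniform(-0.15, 0.15, size=n_breakpoints) * span
        starts.append(np.clip(psi0 + jitter, lo + 0.05 * span, hi - 0.05 * span))
    # coarse RSS scan over interior quantile candidates: a cheap global start
    # that protects the linearization from local minima on weak signals
    grid = np.unique(np.quantile(x, np.linspace(0.05, 0.95, 25)))
    grid = grid[(grid > lo) & (grid < hi)]
    best_start, best_start_rss = None, np.inf
    if n_breakpoints == 1:
        cand = [(g,) for g in grid]
    else:
        cand = [(a, b) for i, a in enumerate(grid) for b in grid[i + 2:]]
    def profile_rss(psi_vec) -> float:
        X = _segmented_design(x, np.asarray(psi_vec), gaps=False)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        return float(np.sum((yv - X @ beta) ** 2))

    scored = sorted(cand, key=profile_rss)
    for c in scored[:3]:
        starts.append(np.asarray(c, dtype=float))
    if n_breakpoints == 1:
        # polish the best candidates by bounded 1-d profile minimization
        from scipy import optimize as _opt
        gstep = span / max(len(grid) - 1, 1)
        for c in scored[:3]:
            res = _opt.minimize_scalar(
                lambda p: profile_rss([p]),
                bounds=(max(lo + 1e-6, c[0] - 2 * gstep),
                        min(hi - 1e-6, c[0] + 2 * gstep)),
                method="bounded",
            )
            if res.success:
                starts.append(np.array([float(res.x)]))

    best: SegmentedFit | None = None
    for s in starts:
        fit = _fit_once(x, yv, s)
        if fit is None:
            continue
        if best is None or fit.rss < best.rss - 1e-12 or (
            fit.converged and not best.converged and fit.rss <= best.rss * 1.001
        ):
            best = fit
    if best is None:
        raise ValueError("segmented fit failed from every start "
                         "(all observations on one side of every candidate?)")
    return best


def breakpoint_confint(fit: SegmentedFit, level: float = 0.95) -> list:
    """Delta-method Wald intervals psi_hat +/- z * SE(gamma)/|delta|."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for p, se in zip(fit.psi, fit.psi_se):
        if not np.isfinite(se) or se == 0 and "not converged" in fit.flags:
            out.append((np.nan, np.nan))
        else:
            out.append((float(p - z * se), float(p + z * se)))
    return out


def segment_slopes(fit: SegmentedFit, level: float = 0.95) -> pd.DataFrame:
    """Slope, SE, and CI per segment; consecutive slopes differ by delta_k."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    bounds = [fit.x_range[0], *fit.psi, fit.x_range[1]]
    for seg in range(fit.n_breakpoints + 1):
        s, se = float(fit.slopes[seg]), float(fit.slope_se[seg])
        rows.append({
            "segment": seg + 1,
            "from_age": float(bounds[seg]),
            "to_age": float(bounds[seg + 1]),
            "slope": s,
            "se": se,
            "ci_lo": s - z * se,
            "ci_hi": s + z * se,
        })
    return pd.DataFrame(rows)


def compare_breakpoints(ci_a: tuple, ci_b: tuple) -> bool:
    """True iff the two closed intervals do not overlap (significant difference)."""
    (lo_a, hi_a), (lo_b, hi_b) = ci_a, ci_b
    if any(not np.isfinite(v) for v in (lo_a, hi_a, lo_b, hi_b)):
        raise ValueError("both confidence intervals must be defined")
    return max(lo_a, lo_b) > min(hi_a, hi_b)


# ---------------------------------------------------------------------------
# Breakpoint-count selection


@dataclass
class BreakpointSelection:
    """Outcome of sequential 0 vs >=1 vs 2 breakpoint testing."""

    n_breakpoints: int
    p_raw: list
    p_adjusted: list
    trend: bool          # first undecided stage significant at 0.1 only
    labels: list


def select_breakpoints(age, y, alpha: float = 0.05, max_breakpoints: int = 2,
                       k: int = 10) -> BreakpointSelection:
    """Sequential Davies tests with Bonferroni correction across stages.

    Stage 1 tests no-breakpoint vs at-least-one on the linear base model;
    if rejected, stage 2 tests one vs two by probing for a second slope
    change over the one-breakpoint model's design.
    """
    x = np.asarray(age, dtype=float)
    yv = np.asarray(y, dtype=float)
    m = int(max_breakpoints)

    p1 = davies_test(x, yv, k=k)
    p_raw, p_adj, labels = [p1], [min(1.0, m * p1)], ["0 vs >=1"]
    chosen = 0
    trend = False
    if p_adj[0] < alpha:
        chosen = 1
    elif p_adj[0] < 0.1:
        trend = True

    if chosen == 1 and m >= 2:
        fit1 = fit_segmented(x, yv, 1)
        base = _segmented_design(x, fit1.psi, gaps=False)
        try:
            p2 = davies_test(x, yv, base_design=base, k=k)
        except ValueError:
            p2 = 1.0
        p_raw.append(p2)
        p_adj.append(min(1.0, m * p2))
        labels.append("1 vs 2")
        if p_adj[1] < alpha:
            chosen = 2
    return BreakpointSelection(
        n_breakpoints=chosen, p_raw=p_raw, p_adjusted=p_adj,
        trend=trend, labels=labels,
    )
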
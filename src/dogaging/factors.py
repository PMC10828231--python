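"""Exploratory factor analysis: principal axis factoring with varimax rotation.

Implements the classical common-factor workflow used on the survey items:
Pearson correlations on listwise-complete rows, Kaiser-Meyer-Olkin sampling
adequacy, Bartlett's sphericity test, iterated principal-axis extraction with
squared-multiple-correlation priors, varimax rotation with Kaiser row
normalization, eigenvalue>1 factor retention with stepwise pruning of items
whose best rotated loading is <= 0.4, Cronbach's alpha per factor, and
regression-method factor scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorModel",
    "correlation_matrix",
    "kmo",
    "bartlett_sphericity",
    "extract_paf",
    "varimax_rotate",
    "retain_and_prune",
    "cronbach_alpha",
    "regression_scores",
    "explained_variance",
    "implied_correlation",
]


def correlation_matrix(items: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations on listwise-complete rows."""
    if items.shape[1] < 2:
        raise ValueError("need at least two items")
    complete = items.dropna()
    if len(complete) < 3:
        raise ValueError("need at least three complete rows")
    sd = complete.std(ddof=1)
    dead = sd[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance item(s): {list(dead.index)}")
    return complete.corr(method="pearson")


def implied_correlation(loadings: np.ndarray) -> np.ndarray:
    """Population correlation matrix implied by a loading pattern: LL' + Psi."""
    L = np.asarray(loadings, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    R = L @ L.T
    np.fill_diagonal(R, 1.0)
    return R


def kmo(R) -> tuple[float, np.ndarray]:
    """Overall and per-item Kaiser-Meyer-Olkin measures of sampling adequacy."""
    R = np.asarray(R, dtype=float)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is singular") from e
    d = 1.0 / np.sqrt(np.diag(Rinv))
    partial = -Rinv * np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    r2 = R**2
    np.fill_diagonal(r2, 0.0)
    a2 = partial**2
    overall = r2.sum() / (r2.sum() + a2.sum())
    per_item = r2.sum(axis=0) / (r2.sum(axis=0) + a2.sum(axis=0))
    return float(overall), per_item


def bartlett_sphericity(R, n: int) -> tuple[float, int, float]:
    """Bartlett's test that R is an identity: chi2, df, upper-tail p."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need more observations than items")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(max(chi2, 0.0), df))
    return float(max(chi2, 0.0)), int(df), pval


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations: 1 - 1/diag(R^-1)."""
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        # fall back to max absolute row correlation as prior communality
        A = np.abs(R - np.eye(len(R)))
        return A.max(axis=0) ** 2
    return 1.0 - 1.0 / np.diag(Rinv)


def extract_paf(
    R, n_factors: int, tol: float = 1e-4, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Iterated principal-axis factoring on the reduced correlation matrix.

    Returns (loadings, eigenvalues of the final reduced matrix, communalities,
    info).  Heywood cases are capped at 1 and flagged; non-convergence is
    flagged, never raised.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must be in [1, n_items)")
    h2 = np.clip(_smc(R), 0.0, 1.0)
    info = {"converged": False, "iterations": 0, "heywood": False}
    loadings = np.zeros((p, n_factors))
    eigs = np.zeros(p)
    for it in range(1, max_iter + 1):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        lam = V[:, :n_factors] * np.sqrt(np.maximum(w[:n_factors], 0.0))
        new_h2 = (lam**2).sum(axis=1)
        if np.any(new_h2 > 1.0):
            info["heywood"] = True
            new_h2 = np.minimum(new_h2, 1.0)
        delta = np.max(np.abs(new_h2 - h2))
        h2, loadings, eigs = new_h2, lam, w
        info["iterations"] = it
        if delta < tol:
            info["converged"] = True
            break
    # deterministic sign: largest-magnitude loading in each factor positive
    for j in range(n_factors):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    return loadings, eigs, h2, info


def varimax_rotate(L, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation with Kaiser row normalization."""
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy()
    norms = np.sqrt((L**2).sum(axis=1))
    norms[norms == 0] = 1.0
    A = L / norms[:, None]
    T = np.eye(k)
    crit_old = 0.0
    for _ in range(max_iter):
        B = A @ T
        U, s, Vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        T = U @ Vt
        crit = s.sum()
        if crit_old != 0 and (crit - crit_old) < tol * crit_old:
            break
        crit_old = crit
    rotated = (A @ T) * norms[:, None]
    # order factors by explained variance, sign-fix as in extraction
    order = np.argsort((rotated**2).sum(axis=0))[::-1]
    rotated = rotated[:, order]
    for j in range(rotated.shape[1]):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] *= -1
    return rotated


def varimax_criterion(L) -> float:
    """Raw varimax criterion (sum of column variances of squared loadings)."""
    L2 = np.asarray(L, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def cronbach_alpha(items: pd.DataFrame) -> float:
    """alpha = p/(p-1) * (1 - sum item variances / variance of the sum)."""
    X = items.dropna().to_numpy(dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least two items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return float(p / (p - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def regression_scores(Z: np.ndarray, L: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Regression-method factor scores: S = Z R^-1 L (mean zero, variance < 1)."""
    R = np.asarray(R, dtype=float)
    try:
        W = np.linalg.solve(R, np.asarray(L, dtype=float))
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is singular") from e
    return np.asarray(Z, dtype=float) @ W


def explained_variance(eigenvalues, n_items: int) -> tuple[np.ndarray, float]:
    """Per-factor percentage (eigenvalue / item count * 100) and cumulative."""
    ev = np.asarray(eigenvalues, dtype=float) / n_items * 100.0
    return ev, float(ev.sum())


@dataclass
class FactorModel:
    """A fitted EFA: loadings, adequacy and reliability statistics."""

    items: list
    n_factors: int
    loadings_unrotated: np.ndarray
    loadings: np.ndarray          # rotated (varimax) when n_factors > 1
    eigenvalues: np.ndarray       # correlation-matrix eigenvalues
    communalities: np.ndarray
    explained_pct: np.ndarray
    cumulative_pct: float
    kmo_overall: float
    kmo_per_item: np.ndarray
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    alphas: list
    rotation: str
    dropped_items: list = field(default_factory=list)
    scores: pd.DataFrame | None = None
    correlation: np.ndarray | None = None

    def score_for(self, anchor_items: list, data: pd.DataFrame) -> pd.Series:
        """Score of the factor on which most anchor items load, sign-aligned
        so it correlates positively with the anchors' mean rating."""
        if self.scores is None:
            raise ValueError("model fitted without scores")
        counts = [
            sum(1 for it in self.factor_items(j) if it in anchor_items)
            for j in range(self.n_factors)
        ]
        j = int(np.argmax(counts))
        s = self.scores[f"factor{j + 1}"]
        anchors = [it for it in anchor_items if it in data.columns]
        anchor_mean = data.loc[s.index, anchors].mean(axis=1)
        if np.corrcoef(s, anchor_mean)[0, 1] < 0:
            s = -s
        return s

    def factor_items(self, j: int, threshold: float = 0.4) -> list:
        """Items loading above threshold on factor j."""
        m = np.abs(self.loadings[:, j]) > threshold
        return [it for it, keep in zip(self.items, m) if keep]

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "n_factors": self.n_factors,
            "loadings": np.asarray(self.loadings).tolist(),
            "eigenvalues": np.asarray(self.eigenvalues).tolist(),
            "communalities": np.asarray(self.communalities).tolist(),
            "explained_pct": np.asarray(self.explained_pct).tolist(),
            "cumulative_pct": self.cumulative_pct,
            "kmo_overall": self.kmo_overall,
            "bartlett": {
                "chi2": self.bartlett_chi2,
                "df": self.bartlett_df,
                "p": self.bartlett_p,
            },
            "alphas": list(self.alphas),
            "rotation": self.rotation,
            "dropped_items": list(self.dropped_items),
        }


def retain_and_prune(
    items: pd.DataFrame, loading_threshold: float = 0.4,
    compute_scores: bool = True,
) -> FactorModel:
    """Eigenvalue>1 retention + stepwise pruning of weak-loading items.

    Repeats: compute correlation matrix, retain factors with eigenvalue > 1,
    extract (PAF) and varimax-rotate, drop the single item with the smallest
    best loading if it is <= the threshold; stops when all items load.
    """
    work = items.copy()
    dropped: list = []
    while True:
        if work.shape[1] < 3:
            raise ValueError("fewer than three items remain; all pruned?")
        Rdf = correlation_matrix(work)
        R = Rdf.to_numpy()
        eig = np.sort(np.linalg.eigvalsh(R))[::-1]
        k = max(1, int((eig > 1.0).sum()))
        loadings, _, h2, info = extract_paf(R, k)
        rotated = varimax_rotate(loadings) if k > 1 else loadings
        best = np.abs(rotated).max(axis=1)
        if best.min() > loading_threshold:
            break
        worst = int(np.argmin(best))
        dropped.append(work.columns[worst])
        work = work.drop(columns=work.columns[worst])

    n_complete = len(work.dropna())
    overall_kmo, per_item_kmo = kmo(R)
    chi2, df_b, p_b = bartlett_sphericity(R, n_complete)
    pct, cum = explained_variance(eig[:k], work.shape[1])

    alphas = []
    for j in range(k):
        members = [work.columns[i] for i in range(work.shape[1])
                   if abs(rotated[i, j]) > loading_threshold]
        alphas.append(cronbach_alpha(work[members]) if len(members) >= 2 else np.nan)

    scores = None
    if compute_scores:
        complete = work.dropna()
        Z = (complete - complete.mean()) / complete.std(ddof=1)
        scores = pd.DataFrame(
            regression_scores(Z.to_numpy(), rotated, R),
            index=complete.index,
            columns=[f"factor{j + 1}" for j in range(k)],
        )

    return FactorModel(
        items=list(work.columns),
        n_factors=k,
        loadings_unrotated=loadings,
        loadings=rotated,
        eigenvalues=eig,
        communalities=h2,
        explained_pct=pct,
        cumulative_pct=cum,
        kmo_overall=overall_kmo,
        kmo_per_item=per_item_kmo,
        bartlett_chi2=chi2,
        bartlett_df=df_b,
        bartlett_p=p_b,
        alphas=alphas,
        rotation="varimax" if k > 1 else "none",
        dropped_items=dropped,
        scores=scores,
        correlation=R,
    )
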
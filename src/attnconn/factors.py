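"""Exploratory factor analysis of Timeline-Followback substance-use items.

Past-30-day consumption counts (alcohol, tobacco, cannabis items at wave 1;
plus cocaine, ecstasy, ketamine later) are screened for sampling adequacy
(per-item KMO >= 0.5, non-degenerate SD), checked for an underlying
correlation structure (Bartlett's sphericity test), reduced by
principal-component extraction (Kaiser eigenvalue-greater-than-1 retention
by default), varimax-rotated with Kaiser normalization, and scored by the
regression method. In the cohorts this module emulates, tobacco and
cannabis co-load on one factor ("Cig+CB"), alcohol on another, and the
hard-drug items on a third at the later waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from attnconn.errors import DegenerateInputError

KMO_MIN = 0.5


@dataclass
class FactorSolution:
    items: list[str]
    eigenvalues: np.ndarray
    loadings: np.ndarray            # unrotated, items x factors
    rotated_loadings: np.ndarray
    rotation_matrix: np.ndarray
    scores: pd.DataFrame            # subjects x factors
    kmo_overall: float
    kmo_per_item: pd.Series
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n_factors: int
    dropped_items: list[str] = field(default_factory=list)
    factor_labels: list[str] = field(default_factory=list)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rotated_loadings, index=self.items,
                            columns=self.factor_labels)


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R| on p(p-1)/2 degrees of freedom.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("sample size must exceed the number of items")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def kmo(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy: overall and per item.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, where q
    are the anti-image partial correlations; the per-item statistic
    restricts both sums to that item's row.
    """
    R = np.asarray(R, dtype=float)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    np.fill_diagonal(Q, 0.0)
    R0 = R - np.diag(np.diag(R))
    r2 = R0**2
    q2 = Q**2
    overall = r2.sum() / (r2.sum() + q2.sum())
    denom = r2.sum(axis=1) + q2.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_item = np.where(denom > 0, r2.sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(overall), per_item


def efa_principal(
    R: np.ndarray, n_factors: int | Literal["auto"] = "auto"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Principal-component extraction from a correlation matrix.

    Returns (loadings, eigenvalues, n_factors); loadings are eigenvectors
    scaled by sqrt(eigenvalue). ``auto`` keeps eigenvalues > 1 (Kaiser).
    """
    R = np.asarray(R, dtype=float)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[-1] < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    eigval = np.clip(eigval, 0.0, None)
    if n_factors == "auto":
        n_factors = int(np.sum(eigval > 1.0)) or 1
    if n_factors > R.shape[0]:
        raise ValueError("n_factors exceeds the number of items")
    # deterministic sign: largest-|loading| item positive per component
    L = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L, eigval, int(n_factors)


def _varimax_criterion(L: np.ndarray) -> float:
    p = L.shape[0]
    L2 = L**2
    return float(np.sum(L2**2) - np.sum(L2.sum(axis=0) ** 2) / p)


def varimax_rotate(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (orthogonal), optionally with Kaiser normalization.

    Classic pairwise (Jacobi-style) algorithm: for every factor pair the
    closed-form planar angle maximizing the varimax criterion is applied,
    sweeping until the criterion stops improving. Row communalities are
    invariant because the rotation matrix is orthogonal. A single factor
    returns the identity rotation with a warning.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        warnings.warn("varimax with one factor is the identity", stacklevel=2)
        return L, np.eye(k)
    comm = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    R = np.eye(k)
    Lr = L.copy()
    crit_old = _varimax_criterion(Lr)
    for _ in range(max_iter):
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = Lr[:, a], Lr[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (u @ v - u.sum() * v.sum() / p)
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                Lr[:, [a, b]] = Lr[:, [a, b]] @ G
                R[:, [a, b]] = R[:, [a, b]] @ G
        crit = _varimax_criterion(Lr)
        if crit - crit_old < tol * max(abs(crit), 1.0):
            break
        crit_old = crit
    rotated = Lr
    if kaiser_normalize:
        rotated = rotated * np.where(comm > 0, comm, 1.0)[:, None]
    # deterministic column order/sign: by explained variance, dominant + sign
    order = np.argsort(-(rotated**2).sum(axis=0), kind="stable")
    rotated = rotated[:, order]
    R = R[:, order]
    for j in range(k):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
            R[:, j] = -R[:, j]
    return rotated, R


def factor_scores(
    data: pd.DataFrame, rotated_loadings: np.ndarray, R: np.ndarray
) -> np.ndarray:
    """Regression-method factor scores on standardized items (mean 0)."""
    if data.isna().any().any():
        raise ValueError("missing item values; screen items upstream")
    Z = stats.zscore(data.to_numpy(float), axis=0, ddof=1)
    W = np.linalg.solve(R, rotated_loadings)
    return Z @ W


def run_efa(
    data: pd.DataFrame,
    n_factors: int | Literal["auto"] = "auto",
    kmo_min: float = KMO_MIN,
    corr_method: Literal["pearson", "spearman"] = "pearson",
) -> FactorSolution:
    """Full EFA pipeline: screen items, test, extract, rotate, score."""
    df = data.copy()
    dropped: list[str] = []
    degenerate = [c for c in df.columns if df[c].std(ddof=1) < 1e-12]
    dropped += degenerate
    df = df.drop(columns=degenerate)
    if df.shape[1] < 3:
        raise DegenerateInputError("fewer than 3 usable items after screening")
    # iterative KMO screening: drop the worst inadequate item, recompute
    while True:
        R = df.corr(method=corr_method).to_numpy()
        overall, per_item = kmo(R)
        worst = int(np.argmin(per_item))
        if per_item[worst] >= kmo_min or df.shape[1] <= 3:
            break
        dropped.append(df.columns[worst])
        df = df.drop(columns=df.columns[worst])
    n = len(df)
    chi2, bdf, bp = bartlett_sphericity(R, n)
    L, eigval, nf = efa_principal(R, n_factors)
    if nf >= 2:
        rotated, rot = varimax_rotate(L)
    else:
        rotated, rot = L, np.eye(1)
    labels = [f"factor{j + 1}" for j in range(nf)]
    scores = factor_scores(df, rotated, R)
    return FactorSolution(
        items=list(df.columns),
        eigenvalues=eigval,
        loadings=L,
        rotated_loadings=rotated,
        rotation_matrix=rot,
        scores=pd.DataFrame(scores, index=data.index, columns=labels),
        kmo_overall=overall,
        kmo_per_item=pd.Series(per_item, index=df.columns),
        bartlett_chi2=chi2,
        bartlett_df=bdf,
        bartlett_p=bp,
        n_factors=nf,
        dropped_items=dropped,
        factor_labels=labels,
    )
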
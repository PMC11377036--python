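"""Three-wave bivariate latent change score (LCS) modeling.

The model couples an attention construct ``a`` (ICV or a network strength)
and a substance-use construct ``s`` over three waves. Latent true scores
carry unit loadings on the single observed indicator per wave, so the
structural part reduces to a path model on the six observed variables:

    delta_a(t -> t+1) = alpha_a(t) + beta_a * a(t) + gamma1 * s(t) + e_a
    delta_s(t -> t+1) = alpha_s(t) + beta_s * s(t) + gamma2 * a(t) + e_s

gamma1 is the lagged effect of substance use on change in attention, gamma2
the lagged effect of attention on change in substance use; beta_* are
proportional-change self-feedbacks, constant across transitions. Wave-1
means/variances/covariance are free, residual (co)variances are free per
transition. That yields 19 free parameters against 27 observed moments
(6 means + 21 covariances), i.e. 8 degrees of freedom.

Estimation minimizes the normal-theory ML discrepancy

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p + (m - mu)' Sigma^-1 (m - mu)

by L-BFGS-B with a data-driven start (pooled OLS of the observed change
regressions) plus random restarts; chi2 = (n - 1) * F_min, standard errors
from the inverse numerical information, standardized coefficients via
model-implied variances. Covariates (age, sex, site) are regressed out of
each observed score per wave, preserving means, before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from attnconn.association import bh_fdr
from attnconn.errors import ConvergenceError, DegenerateInputError

OBS_ORDER = ("a1", "s1", "a2", "s2", "a3", "s3")

PARAM_NAMES = (
    "mu_a1", "mu_s1",
    "alpha_a2", "alpha_s2", "alpha_a3", "alpha_s3",
    "var_a1", "var_s1", "cov_as1",
    "beta_a", "beta_s", "gamma1", "gamma2",
    "psi_a2", "psi_s2", "psi_as2",
    "psi_a3", "psi_s3", "psi_as3",
)
_VARIANCE_PARAMS = ("var_a1", "var_s1", "psi_a2", "psi_s2", "psi_a3", "psi_s3")
N_PARAMS = len(PARAM_NAMES)
N_OBS = len(OBS_ORDER)
N_MOMENTS = N_OBS + N_OBS * (N_OBS + 1) // 2
MODEL_DF = N_MOMENTS - N_PARAMS


@dataclass
class LCSModelSpec:
    """Free-parameter inventory of the bivariate three-wave LCS model."""

    attention: str = "a"
    substance: str = "s"
    covariate_names: tuple[str, ...] = ()
    param_names: tuple[str, ...] = PARAM_NAMES
    n_waves: int = 3

    @property
    def n_free_parameters(self) -> int:
        return len(self.param_names)

    @property
    def degrees_of_freedom(self) -> int:
        return N_MOMENTS - len(self.param_names)

    def to_dict(self) -> dict:
        return {
            "attention": self.attention,
            "substance": self.substance,
            "covariate_names": list(self.covariate_names),
            "param_names": list(self.param_names),
            "n_waves": self.n_waves,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCSModelSpec":
        return cls(
            attention=d["attention"],
            substance=d["substance"],
            covariate_names=tuple(d["covariate_names"]),
            param_names=tuple(d["param_names"]),
            n_waves=d["n_waves"],
        )


def build_lcs_spec(
    data: pd.DataFrame,
    covariates: Optional[Mapping[str, pd.DataFrame]] = None,
    attention: str = "a",
    substance: str = "s",
) -> LCSModelSpec:
    """Validate a wide pair table (columns a1..a3, s1..s3) into a spec."""
    waves = sorted(
        {int(c[1:]) for c in data.columns if c[:1] in ("a", "s") and c[1:].isdigit()}
    )
    if waves != [1, 2, 3]:
        raise DegenerateInputError(
            f"bivariate LCS requires exactly 3 waves of both constructs, "
            f"got waves {waves}"
        )
    missing = [c for c in OBS_ORDER if c not in data.columns]
    if missing:
        raise ValueError(f"missing observed columns {missing}")
    covnames: tuple[str, ...] = ()
    if covariates:
        covnames = tuple(
            sorted({c for tab in covariates.values() for c in tab.columns})
        )
    return LCSModelSpec(attention=attention, substance=substance,
                        covariate_names=covnames)


# ---------------------------------------------------------------------------
# Implied moments


def implied_moments(theta: np.ndarray | Mapping[str, float]):
    """Model-implied mean vector and covariance of (a1,s1,a2,s2,a3,s3).

    Returns (mu, Sigma, admissible); inadmissible parameter values
    (negative variances or residual correlations outside [-1, 1]) are
    flagged, not clipped.
    """
    if isinstance(theta, Mapping):
        t = np.array([theta[k] for k in PARAM_NAMES], dtype=float)
    else:
        t = np.asarray(theta, dtype=float)
    p = dict(zip(PARAM_NAMES, t))
    admissible = all(p[k] >= 0 for k in _VARIANCE_PARAMS)
    for cov, va, vs in (
        ("cov_as1", "var_a1", "var_s1"),
        ("psi_as2", "psi_a2", "psi_s2"),
        ("psi_as3", "psi_a3", "psi_s3"),
    ):
        bound = np.sqrt(max(p[va], 0.0) * max(p[vs], 0.0))
        if abs(p[cov]) > bound + 1e-12:
            admissible = False

    T = np.array([[1.0 + p["beta_a"], p["gamma1"]],
                  [p["gamma2"], 1.0 + p["beta_s"]]])
    mu1 = np.array([p["mu_a1"], p["mu_s1"]])
    mu2 = np.array([p["alpha_a2"], p["alpha_s2"]]) + T @ mu1
    mu3 = np.array([p["alpha_a3"], p["alpha_s3"]]) + T @ mu2
    S11 = np.array([[p["var_a1"], p["cov_as1"]], [p["cov_as1"], p["var_s1"]]])
    P2 = np.array([[p["psi_a2"], p["psi_as2"]], [p["psi_as2"], p["psi_s2"]]])
    P3 = np.array([[p["psi_a3"], p["psi_as3"]], [p["psi_as3"], p["psi_s3"]]])
    S21 = T @ S11
    S22 = T @ S11 @ T.T + P2
    S31 = T @ S21
    S32 = T @ S22
    S33 = T @ S22 @ T.T + P3

    mu = np.concatenate([mu1, mu2, mu3])
    Sigma = np.zeros((6, 6))
    Sigma[0:2, 0:2] = S11
    Sigma[2:4, 0:2] = S21
    Sigma[0:2, 2:4] = S21.T
    Sigma[2:4, 2:4] = S22
    Sigma[4:6, 0:2] = S31
    Sigma[0:2, 4:6] = S31.T
    Sigma[4:6, 2:4] = S32
    Sigma[2:4, 4:6] = S32.T
    Sigma[4:6, 4:6] = S33
    return mu, Sigma, admissible


def _ml_discrepancy(theta, S, m, logdet_S):
    mu, Sigma, _ = implied_moments(theta)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Sinv_S = np.linalg.solve(Sigma, S)
    diff = m - mu
    quad = diff @ np.linalg.solve(Sigma, diff)
    f = logdet + np.trace(Sinv_S) - logdet_S - N_OBS + quad
    return f if np.isfinite(f) else 1e10


def _default_start(S: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Moment-only start: wave-1 block from S/m, zero dynamics."""
    p = {k: 0.0 for k in PARAM_NAMES}
    p.update(
        mu_a1=m[0], mu_s1=m[1],
        alpha_a2=m[2] - m[0], alpha_s2=m[3] - m[1],
        alpha_a3=m[4] - m[2], alpha_s3=m[5] - m[3],
        var_a1=S[0, 0], var_s1=S[1, 1], cov_as1=S[0, 1],
        psi_a2=S[2, 2] / 2, psi_s2=S[3, 3] / 2,
        psi_a3=S[4, 4] / 2, psi_s3=S[5, 5] / 2,
    )
    return np.array([p[k] for k in PARAM_NAMES])


def _start_values(data: np.ndarray) -> np.ndarray:
    """Data-driven start: moments for wave 1, pooled OLS for the dynamics."""
    a1, s1, a2, s2, a3, s3 = (data[:, i] for i in range(6))
    p = {}
    p["mu_a1"], p["mu_s1"] = a1.mean(), s1.mean()
    p["var_a1"] = a1.var(ddof=1)
    p["var_s1"] = s1.var(ddof=1)
    p["cov_as1"] = np.cov(a1, s1, ddof=1)[0, 1]

    def trans(prev_a, prev_s, next_a, next_s):
        X = np.column_stack([np.ones(len(prev_a)), prev_a, prev_s])
        ba, _, _, _ = np.linalg.lstsq(X, next_a - prev_a, rcond=None)
        bs, _, _, _ = np.linalg.lstsq(X, next_s - prev_s, rcond=None)
        ra = next_a - prev_a - X @ ba
        rs = next_s - prev_s - X @ bs
        return ba, bs, ra.var(ddof=1), rs.var(ddof=1), np.cov(ra, rs, ddof=1)[0, 1]

    ba2, bs2, va2, vs2, c2 = trans(a1, s1, a2, s2)
    ba3, bs3, va3, vs3, c3 = trans(a2, s2, a3, s3)
    p["alpha_a2"], p["alpha_s2"] = ba2[0], bs2[0]
    p["alpha_a3"], p["alpha_s3"] = ba3[0], bs3[0]
    p["beta_a"] = (ba2[1] + ba3[1]) / 2
    p["beta_s"] = (bs2[2] + bs3[2]) / 2
    p["gamma1"] = (ba2[2] + ba3[2]) / 2
    p["gamma2"] = (bs2[1] + bs3[1]) / 2
    p["psi_a2"], p["psi_s2"], p["psi_as2"] = va2, vs2, c2
    p["psi_a3"], p["psi_s3"], p["psi_as3"] = va3, vs3, c3
    return np.array([p[k] for k in PARAM_NAMES])


@dataclass
class LCSFit:
    """ML estimates, standard errors, and fit statistics for one pair."""

    params: dict[str, float]
    se: dict[str, float]
    std_params: dict[str, float]
    chi2: float
    df: int
    n: int
    f_min: float
    converged: bool
    mu_hat: np.ndarray
    sigma_hat: np.ndarray
    sample_mean: np.ndarray
    sample_cov: np.ndarray
    cfi: float = float("nan")
    rmsea: float = float("nan")
    srmr: float = float("nan")
    pvalues: dict[str, float] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for k in PARAM_NAMES:
            rows.append(
                {
                    "parameter": k,
                    "estimate": self.params[k],
                    "se": self.se.get(k, float("nan")),
                    "std_beta": self.std_params.get(k, float("nan")),
                    "p": self.pvalues.get(k, float("nan")),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def _residualize_preserving_mean(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Remove covariate effects but keep the variable's mean."""
    Cc = C - C.mean(axis=0)
    beta, _, _, _ = np.linalg.lstsq(
        np.hstack([np.ones((len(y), 1)), Cc]), y, rcond=None
    )
    return y - Cc @ beta[1:]


def _covariate_matrix(tab: pd.DataFrame) -> np.ndarray:
    cols = []
    for c in ("age", "sex", "mean_fd", "pds"):
        if c in tab.columns:
            cols.append(tab[c].to_numpy(float))
    if "site" in tab.columns:
        for lev in sorted(tab["site"].unique())[1:]:
            cols.append((tab["site"] == lev).to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(tab), 0))


def adjust_for_covariates(
    data: pd.DataFrame, covariates: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Regress wave-matched covariates out of each observed score."""
    out = data.copy()
    for col in OBS_ORDER:
        wave = col[1:]
        tab = covariates.get(wave)
        if tab is None:
            tab = covariates.get(int(wave))
        if tab is None:
            continue
        C = _covariate_matrix(tab.loc[data.index])
        if C.shape[1]:
            out[col] = _residualize_preserving_mean(
                data[col].to_numpy(float), C
            )
    return out


def fit_ml(
    data: pd.DataFrame,
    covariates: Optional[Mapping[str, pd.DataFrame]] = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-10,
    compute_se: bool = True,
) -> LCSFit:
    """Maximum-likelihood fit of the bivariate LCS model.

    ``data`` holds complete cases with columns a1..a3 (attention) and
    s1..s3 (substance). The first optimization start is data-driven (pooled
    OLS of the change regressions); remaining restarts jitter it. Raises
    :class:`ConvergenceError` if no restart converges.
    """
    data = data.dropna(subset=list(OBS_ORDER))
    if covariates:
        data = adjust_for_covariates(data, covariates)
    arr = data[list(OBS_ORDER)].to_numpy(float)
    n = arr.shape[0]
    if n <= N_PARAMS + 10:
        raise DegenerateInputError(
            f"n={n} too small for {N_PARAMS} free parameters"
        )
    S = np.cov(arr, rowvar=False, ddof=1)
    m = arr.mean(axis=0)
    return fit_ml_moments(S, m, n, x0=_start_values(arr),
                          n_restarts=n_restarts, seed=seed, tol=tol,
                          compute_se=compute_se)


def fit_ml_moments(
    S: np.ndarray,
    m: np.ndarray,
    n: int,
    x0: Optional[np.ndarray] = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-10,
    compute_se: bool = True,
) -> LCSFit:
    """Fit the LCS model directly to a sample mean vector and covariance.

    This is the moment-level core of :func:`fit_ml`; feeding it
    model-implied moments recovers the generating parameters exactly
    (discrepancy zero), which serves as the estimator's self-consistency
    check.
    """
    S = np.asarray(S, dtype=float)
    m = np.asarray(m, dtype=float)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegenerateInputError("sample covariance is singular")
    if x0 is None:
        x0 = _default_start(S, m)

    bounds = [
        (1e-8, None) if k in _VARIANCE_PARAMS else (None, None)
        for k in PARAM_NAMES
    ]
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(n_restarts, 1)):
        start = x0 if trial == 0 else x0 * (1 + 0.1 * rng.standard_normal(N_PARAMS))
        start = np.array([
            max(v, 1e-6) if k in _VARIANCE_PARAMS else v
            for k, v in zip(PARAM_NAMES, start)
        ])
        res = optimize.minimize(
            _ml_discrepancy, start, args=(S, m, logdet_S),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise ConvergenceError(
            f"LCS fit failed to converge; best F = {getattr(best, 'fun', np.inf)}"
        )
    theta = best.x
    params = dict(zip(PARAM_NAMES, theta))
    mu_hat, sigma_hat, _ = implied_moments(theta)

    se = {}
    pvalues = {}
    if compute_se:
        H = _numerical_hessian(
            lambda t: _ml_discrepancy(t, S, m, logdet_S), theta
        )
        info = (n - 1) / 2.0 * H
        try:
            cov_theta = np.linalg.inv(info)
            diag = np.clip(np.diag(cov_theta), 0.0, None)
            se = dict(zip(PARAM_NAMES, np.sqrt(diag)))
        except np.linalg.LinAlgError:
            se = {k: float("nan") for k in PARAM_NAMES}
        for k in PARAM_NAMES:
            s = se.get(k, float("nan"))
            if s and np.isfinite(s) and s > 0:
                z = params[k] / s
                pvalues[k] = float(2 * stats.norm.sf(abs(z)))
            else:
                pvalues[k] = float("nan")

    fit = LCSFit(
        params=params,
        se=se,
        std_params=_standardize(params, sigma_hat),
        chi2=float((n - 1) * best.fun),
        df=MODEL_DF,
        n=n,
        f_min=float(best.fun),
        converged=bool(best.success or best.fun < 1e9),
        mu_hat=mu_hat,
        sigma_hat=sigma_hat,
        sample_mean=m,
        sample_cov=S,
        pvalues=pvalues,
    )
    fit.cfi, fit.rmsea, fit.srmr = fit_indices(fit)
    return fit


def _numerical_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    steps = eps * np.maximum(np.abs(x), 1.0)
    for i in range(k):
        for j in range(i, k):
            xi, xj = steps[i], steps[j]
            if i == j:
                xp = x.copy(); xp[i] += xi
                xm = x.copy(); xm[i] -= xi
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / xi**2
            else:
                xpp = x.copy(); xpp[i] += xi; xpp[j] += xj
                xpm = x.copy(); xpm[i] += xi; xpm[j] -= xj
                xmp = x.copy(); xmp[i] -= xi; xmp[j] += xj
                xmm = x.copy(); xmm[i] -= xi; xmm[j] -= xj
                H[i, j] = H[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4 * xi * xj)
    return H


def _standardize(params: dict[str, float], Sigma: np.ndarray) -> dict[str, float]:
    """Standardized dynamic coefficients via model-implied variances.

    For a change regression delta = beta * predictor + ..., the
    standardized coefficient is beta * sd(predictor) / sd(delta), using the
    first transition's implied moments (parameters are transition-
    invariant).
    """
    ia1, is1, ia2, is2 = 0, 1, 2, 3
    var_da = Sigma[ia2, ia2] + Sigma[ia1, ia1] - 2 * Sigma[ia2, ia1]
    var_ds = Sigma[is2, is2] + Sigma[is1, is1] - 2 * Sigma[is2, is1]
    sd = np.sqrt
    out = {}
    if var_da > 0:
        out["gamma1"] = params["gamma1"] * sd(Sigma[is1, is1]) / sd(var_da)
        out["beta_a"] = params["beta_a"] * sd(Sigma[ia1, ia1]) / sd(var_da)
    if var_ds > 0:
        out["gamma2"] = params["gamma2"] * sd(Sigma[ia1, ia1]) / sd(var_ds)
        out["beta_s"] = params["beta_s"] * sd(Sigma[is1, is1]) / sd(var_ds)
    return out


def fit_indices(fit: LCSFit) -> tuple[float, float, float]:
    """CFI, RMSEA, SRMR against the independence baseline.

    Baseline: free means and variances, zero covariances — its discrepancy
    has the closed form sum(ln s_ii) - ln|S|.
    """
    S, n = fit.sample_cov, fit.n
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegenerateInputError("singular sample covariance in baseline")
    f_base = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_b = (n - 1) * f_base
    df_b = N_MOMENTS - 2 * N_OBS
    excess = max(fit.chi2 - fit.df, 0.0)
    excess_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 - excess / max(excess_b, excess, np.finfo(float).tiny)
    rmsea = float(np.sqrt(excess / (fit.df * (n - 1))))
    d = np.sqrt(np.diag(S))
    resid = (S - fit.sigma_hat) / np.outer(d, d)
    iu = np.triu_indices(N_OBS)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return float(np.clip(cfi, 0.0, 1.0)), rmsea, srmr


# ---------------------------------------------------------------------------
# Battery


def run_battery(
    attention: Mapping[str, pd.DataFrame],
    substance: Mapping[str, pd.DataFrame],
    covariates: Optional[Mapping[str, pd.DataFrame]] = None,
    q: float = 0.05,
    seed: int = 0,
    n_restarts: int = 5,
) -> pd.DataFrame:
    """Fit every substance x attention pair; FDR across all lagged effects.

    ``attention``/``substance`` map measure name -> wide table with columns
    1, 2, 3 (waves), indexed by subject. With 2 substance factors and 5
    attention measures this is the canonical 10-model battery; the BH-FDR
    family is the 2 x (number of models) lagged-effect p-values.
    """
    rows = []
    fits = {}
    for sname, stab in substance.items():
        for aname, atab in attention.items():
            common = atab.index.intersection(stab.index)
            data = pd.DataFrame(index=common)
            for w in (1, 2, 3):
                data[f"a{w}"] = atab.loc[common].iloc[:, w - 1]
                data[f"s{w}"] = stab.loc[common].iloc[:, w - 1]
            row = {"substance": sname, "attention": aname}
            try:
                fit = fit_ml(data, covariates=covariates, seed=seed,
                             n_restarts=n_restarts)
                fits[(sname, aname)] = fit
                for g in ("gamma1", "gamma2"):
                    row[g] = fit.params[g]
                    row[f"{g}_se"] = fit.se.get(g, float("nan"))
                    row[f"{g}_std"] = fit.std_params.get(g, float("nan"))
                    row[f"{g}_p"] = fit.pvalues.get(g, float("nan"))
                row.update(
                    chi2=fit.chi2, df=fit.df, cfi=fit.cfi, rmsea=fit.rmsea,
                    srmr=fit.srmr, converged=fit.converged, error="",
                )
            except (ConvergenceError, DegenerateInputError, ValueError) as exc:
                row.update(converged=False, error=str(exc))
            rows.append(row)
    table = pd.DataFrame(rows)
    pcols = []
    for g in ("gamma1", "gamma2"):
        if f"{g}_p" in table:
            pcols.append(f"{g}_p")
    pvals, keys = [], []
    for col in pcols:
        for i, v in table[col].items():
            if np.isfinite(v):
                pvals.append(v)
                keys.append((i, col))
    for col in pcols:
        table[col.replace("_p", "_fdr_significant")] = False
    if pvals:
        reject, _ = bh_fdr(pvals, q=q)
        for (i, col), rej in zip(keys, reject):
            table.loc[i, col.replace("_p", "_fdr_significant")] = bool(rej)
    table.attrs["fits"] = fits
    return table
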
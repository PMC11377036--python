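"""Residualized Spearman association grids and quintile trajectories.

Attention measures (ICV, network strengths) and substance-use factor scores
are first residualized on nuisance covariates (age, sex, site, mean FD for
brain measures, mode-centered pubertal stage at wave 1), then correlated by
tie-aware Spearman rank correlation for every wave pair. Benjamini-Hochberg
FDR (q < 0.05) is applied within configurable families — by default one
family per measure/factor grid, matching per-panel reporting.

Quintile trajectories split subjects into five near-equal groups on a
baseline measure and track an outcome's group means across waves; note that
for negative-network strength higher values mean *better* sustained
attention, so the High/Low attention labels flip with polarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from attnconn.errors import DegenerateInputError

DEFAULT_FDR_Q = 0.05
MIN_OVERLAP = 20


@dataclass
class AssociationResult:
    measure: str
    factor: str
    wave_x: str
    wave_y: str
    rho: float
    p: float
    p_adjusted: float = float("nan")
    significant: bool = False
    n: int = 0
    family: str = ""


def residualize(y: np.ndarray, covariates: Optional[pd.DataFrame | np.ndarray]) -> np.ndarray:
    """Residuals of y after OLS on an intercept plus covariate columns."""
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(y), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    X = np.hstack([np.ones((len(y), 1)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular covariate design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware Spearman rho with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need matched samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant input to Spearman correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_fdr(pvals: Sequence[float], q: float = DEFAULT_FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _covariate_matrix(cov: Optional[pd.DataFrame], use_fd: bool) -> Optional[np.ndarray]:
    if cov is None:
        return None
    cols = []
    for c in ("age", "sex", "mean_fd", "pds"):
        if c == "mean_fd" and not use_fd:
            continue
        if c in cov.columns:
            cols.append(cov[c].to_numpy(float))
    if "site" in cov.columns:
        levels = sorted(cov["site"].unique())
        for lev in levels[1:]:
            cols.append((cov["site"] == lev).to_numpy(float))
    return np.column_stack(cols) if cols else None


def cross_wave_association_grid(
    measures: Mapping[str, pd.DataFrame],
    factors: Mapping[str, pd.DataFrame],
    covariates: Mapping[str, pd.DataFrame],
    q: float = DEFAULT_FDR_Q,
    families: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """All wave x wave Spearman correlations, residualized, FDR per family.

    Parameters
    ----------
    measures, factors
        name -> wide table (index = subject id, one column per wave).
    covariates
        wave -> covariate table indexed by subject id (age, sex, site,
        mean_fd, optional pds). Mean FD is used when residualizing brain/
        behavioral measures but not factor scores.
    families
        family name -> list of measure names sharing one FDR correction;
        default is one family per measure.
    """
    rows: list[AssociationResult] = []
    families = families or {m: [m] for m in measures}
    fam_of = {m: f for f, ms in families.items() for m in ms}
    for mname, mtab in measures.items():
        for fname, ftab in factors.items():
            for wx in mtab.columns:
                for wy in ftab.columns:
                    common = mtab.index.intersection(ftab.index)
                    mv = mtab.loc[common, wx]
                    fv = ftab.loc[common, wy]
                    keep = mv.notna() & fv.notna()
                    common = common[keep]
                    if len(common) < MIN_OVERLAP:
                        raise DegenerateInputError(
                            f"overlap n={len(common)} < {MIN_OVERLAP} for "
                            f"({mname}@{wx}, {fname}@{wy})"
                        )
                    cx = covariates.get(str(wx))
                    cy = covariates.get(str(wy))
                    rm = residualize(
                        mv.loc[common].to_numpy(float),
                        None if cx is None else _covariate_matrix(
                            cx.loc[common], use_fd=True
                        ),
                    )
                    rf = residualize(
                        fv.loc[common].to_numpy(float),
                        None if cy is None else _covariate_matrix(
                            cy.loc[common], use_fd=False
                        ),
                    )
                    rho, p = spearman_corr(rm, rf)
                    rows.append(
                        AssociationResult(
                            measure=mname, factor=fname,
                            wave_x=str(wx), wave_y=str(wy),
                            rho=rho, p=p, n=len(common),
                            family=fam_of.get(mname, mname),
                        )
                    )
    df = pd.DataFrame([r.__dict__ for r in rows])
    for fam in df["family"].unique():
        sel = df["family"] == fam
        reject, p_adj = bh_fdr(df.loc[sel, "p"].to_numpy(), q=q)
        df.loc[sel, "p_adjusted"] = p_adj
        df.loc[sel, "significant"] = reject
    return df


def quintile_trajectories(
    baseline: pd.Series,
    outcome_by_wave: pd.DataFrame,
    higher_is_better: bool = False,
    n_groups: int = 5,
) -> pd.DataFrame:
    """Group-by-wave outcome means with 95% CIs for baseline quintiles.

    Subjects are split into ``n_groups`` near-equal groups (sizes within 1)
    by rank on the baseline measure. The top and bottom groups are labeled
    by sustained attention: for ICV and positive-network strength higher
    baseline means *lower* attention (``higher_is_better=False``); for
    negative-network strength the labeling flips.
    """
    common = baseline.index.intersection(outcome_by_wave.index)
    if len(common) < 5 * n_groups:
        raise DegenerateInputError(f"need at least {5 * n_groups} subjects")
    b = baseline.loc[common].to_numpy(float)
    if np.std(b) == 0:
        raise DegenerateInputError("constant baseline measure")
    # >40% of subjects tied at one value makes quantile groups meaningless
    _, counts = np.unique(b, return_counts=True)
    if counts.max() > 0.4 * len(b):
        raise DegenerateInputError(
            "more than 40% ties in the baseline measure; consider rank jitter"
        )
    order = np.argsort(b, kind="stable")
    groups = np.empty(len(b), int)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        groups[chunk] = g
    rows = []
    for g in range(n_groups):
        idx = common[groups == g]
        label = ""
        if g == 0:
            label = "high_attention" if not higher_is_better else "low_attention"
        elif g == n_groups - 1:
            label = "low_attention" if not higher_is_better else "high_attention"
        for wave in outcome_by_wave.columns:
            vals = outcome_by_wave.loc[idx, wave].dropna().to_numpy(float)
            mean = float(np.mean(vals))
            sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            rows.append(
                {
                    "group": g + 1,
                    "attention_label": label,
                    "wave": wave,
                    "n": len(vals),
                    "mean": mean,
                    "ci_low": mean - 1.96 * sem,
                    "ci_high": mean + 1.96 * sem,
                }
            )
    return pd.DataFrame(rows)
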
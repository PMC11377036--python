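"""Connectome-based predictive modeling (CPM) of a behavioral phenotype.

Within every training fold the pipeline (i) computes the partial correlation
of each connectome edge with the phenotype controlling for covariates,
(ii) keeps edges with p below a threshold (default 0.01), split into a
positive and a negative network by the sign of r, (iii) sums each subject's
selected edge values into network strengths (combined = positive minus
negative), and (iv) fits an OLS model phenotype ~ strength + covariates
whose coefficients are applied to held-out subjects. Performance is the
Pearson correlation between predicted and observed phenotype; k-fold CV is
repeated (default 50 times) and the per-repeat correlations averaged.
Inference is by permutation: the phenotype is shuffled and the whole
pipeline re-run to build a null distribution of correlations.

A model trained on the full sample at one wave can be transferred: its edge
masks and linear coefficients are frozen and applied to another wave's (or
cohort's) matrices, with significance from shuffling the predicted values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from attnconn.errors import CollinearityError, DegenerateInputError
from attnconn.gppi import GPPIMatrix

NETWORKS = ("positive", "negative", "combined")

DEFAULT_P_THRESH = 0.01
CONSENSUS_FRACTION = 0.95


# ---------------------------------------------------------------------------
# Edge containers


@dataclass
class CohortEdgeSet:
    """Subjects x vectorized upper-triangle edges for one wave."""

    X: np.ndarray
    n_roi: int
    subject_ids: list[str]
    wave: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        expected = self.n_roi * (self.n_roi - 1) // 2
        if self.X.shape[1] != expected:
            raise ValueError(
                f"edge count {self.X.shape[1]} != n_roi(n_roi-1)/2 = {expected}"
            )

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]

    def edge_pairs(self) -> np.ndarray:
        """(n_edges, 2) array mapping edge index -> (i, j), i < j."""
        iu = np.triu_indices(self.n_roi, k=1)
        return np.column_stack(iu)


def vectorize_matrix(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize(vec: np.ndarray, n_roi: int) -> np.ndarray:
    m = np.zeros((n_roi, n_roi))
    iu = np.triu_indices(n_roi, k=1)
    m[iu] = vec
    return m + m.T


def vectorize_edges(matrices: Sequence[GPPIMatrix], wave: str = "") -> CohortEdgeSet:
    """Stack symmetric matrices into a subjects x edges array."""
    if not matrices:
        raise ValueError("no matrices supplied")
    n_roi = matrices[0].matrix.shape[0]
    model = matrices[0].condition_model
    for gm in matrices:
        if gm.matrix.shape[0] != n_roi or gm.condition_model != model:
            raise ValueError("matrices differ in atlas size or condition model")
    return CohortEdgeSet(
        X=np.vstack([vectorize_matrix(gm.matrix) for gm in matrices]),
        n_roi=n_roi,
        subject_ids=[gm.subject_id for gm in matrices],
        wave=wave,
    )


# ---------------------------------------------------------------------------
# Covariates

COVARIATE_NUMERIC = ("age", "sex", "mean_fd", "pds")


def covariate_design(
    table: Optional[pd.DataFrame],
    include_site: bool = True,
    site_levels: Optional[Sequence] = None,
) -> tuple[np.ndarray, list[str]]:
    """Covariate columns (no intercept): numeric covariates + site dummies.

    Site is one-hot encoded against a reference level (the first of
    ``site_levels``, or the sorted levels present). Rows must be complete.
    """
    if table is None or table.shape[1] == 0:
        return np.empty((0 if table is None else len(table), 0)), []
    cols, names = [], []
    for c in COVARIATE_NUMERIC:
        if c in table.columns:
            v = table[c].to_numpy(float)
            if np.isnan(v).any():
                raise ValueError(f"covariate {c!r} has missing values")
            cols.append(v)
            names.append(c)
    if include_site and "site" in table.columns:
        levels = list(site_levels) if site_levels is not None else sorted(
            table["site"].unique()
        )
        for lev in levels[1:]:
            cols.append((table["site"] == lev).to_numpy(float))
            names.append(f"site_{lev}")
    if not cols:
        return np.empty((len(table), 0)), []
    return np.column_stack(cols), names


def _cov_design(table: Optional[pd.DataFrame], n: int,
                include_site: bool = True) -> tuple[np.ndarray, list[str]]:
    """covariate_design with an explicit row count for the no-covariate case."""
    C, names = covariate_design(table, include_site=include_site)
    if C.shape[1] == 0:
        return np.empty((n, 0)), names
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match number of subjects")
    return C, names


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after OLS on [1, C]."""
    design = np.hstack([np.ones((M.shape[0], 1)), C])
    beta, _, _, _ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ beta


# ---------------------------------------------------------------------------
# Feature selection


@dataclass
class EdgeStats:
    r: np.ndarray
    p: np.ndarray
    df: int
    zero_variance: np.ndarray


@dataclass
class EdgeMask:
    polarity: Literal["positive", "negative"]
    edges: np.ndarray  # sorted edge indices
    p_thresh: float = DEFAULT_P_THRESH
    selection_fraction: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.edges)


def edge_partial_correlations(
    X: np.ndarray, y: np.ndarray, C: np.ndarray
) -> EdgeStats:
    """Per-edge partial Pearson r/p controlling for covariate columns C.

    Implemented by double residualization; p from the t distribution with
    df = n - 2 - k. Zero-variance edges get r = 0, p = 1 and a flag.
    """
    n, k = X.shape[0], C.shape[1]
    if n <= k + 3:
        raise DegenerateInputError(f"n={n} too small for {k} covariates")
    ry = _residualize(y[:, None], C)[:, 0]
    sy = np.sqrt(ry @ ry)
    if sy <= 1e-10 * max(np.sqrt(y @ y), 1e-30):
        raise DegenerateInputError("phenotype has zero residual variance")
    RX = _residualize(X, C)
    sx = np.sqrt(np.einsum("ij,ij->j", RX, RX))
    zero = sx == 0
    sx_safe = np.where(zero, 1.0, sx)
    r = (RX.T @ ry) / (sx_safe * sy)
    r = np.clip(np.where(zero, 0.0, r), -1.0, 1.0)
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, p)
    return EdgeStats(r=r, p=p, df=df, zero_variance=zero)


def select_edges(
    edge_stats: EdgeStats, p_thresh: float = DEFAULT_P_THRESH
) -> tuple[EdgeMask, EdgeMask]:
    pos = np.flatnonzero((edge_stats.p < p_thresh) & (edge_stats.r > 0))
    neg = np.flatnonzero((edge_stats.p < p_thresh) & (edge_stats.r < 0))
    return (
        EdgeMask("positive", pos, p_thresh),
        EdgeMask("negative", neg, p_thresh),
    )


def network_strength(
    edge_values: np.ndarray,
    mask: EdgeMask | np.ndarray,
    negative_mask: Optional[EdgeMask | np.ndarray] = None,
) -> np.ndarray:
    """Sum of masked edge values per subject; combined if two masks given.

    ``edge_values`` may be one subject's vector or a subjects x edges array.
    """
    arr = np.atleast_2d(np.asarray(edge_values, dtype=float))
    idx = mask.edges if isinstance(mask, EdgeMask) else np.asarray(mask, int)
    if len(idx) == 0:
        warnings.warn("empty edge mask; network strength is 0", stacklevel=2)
        s = np.zeros(arr.shape[0])
    else:
        s = arr[:, idx].sum(axis=1)
    if negative_mask is not None:
        s = s - network_strength(arr, negative_mask)
    return s if np.asarray(edge_values).ndim > 1 else float(s[0])


# ---------------------------------------------------------------------------
# Linear model


def fit_predict_linear(
    strength_train: np.ndarray,
    C_train: np.ndarray,
    y_train: np.ndarray,
    strength_test: np.ndarray,
    C_test: np.ndarray,
    refit_covariates: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS phenotype ~ intercept + strength + covariates; predict held-out.

    Returns (test predictions, coefficient vector [intercept, slope,
    covariate slopes]). By default test predictions use the training-frozen
    covariate coefficients; ``refit_covariates`` ignores covariates at
    prediction time (strength term plus intercept only).
    """
    Xtr = np.hstack([np.ones((len(y_train), 1)), strength_train[:, None], C_train])
    if np.std(strength_train) == 0:
        raise CollinearityError("network strength is constant in training data")
    if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
        raise CollinearityError("singular training design in linear model")
    beta, _, _, _ = np.linalg.lstsq(Xtr, y_train, rcond=None)
    if refit_covariates:
        pred = beta[0] + beta[1] * strength_test
    else:
        Xte = np.hstack(
            [np.ones((len(strength_test), 1)), strength_test[:, None], C_test]
        )
        pred = Xte @ beta
    return pred, beta


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CPMModel:
    """Frozen full-sample CPM model (masks + per-network coefficients)."""

    n_roi: int
    p_thresh: float
    positive_edges: np.ndarray
    negative_edges: np.ndarray
    coefficients: dict[str, np.ndarray]  # network -> [intercept, slope, covs...]
    covariate_names: list[str]
    seed: Optional[int] = None
    scheme: str = "full_sample"

    def to_json(self, path) -> None:
        payload = {
            "n_roi": self.n_roi,
            "p_thresh": self.p_thresh,
            "positive_edges": self.positive_edges.tolist(),
            "negative_edges": self.negative_edges.tolist(),
            "coefficients": {k: v.tolist() for k, v in self.coefficients.items()},
            "covariate_names": self.covariate_names,
            "seed": self.seed,
            "scheme": self.scheme,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CPMModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_roi=d["n_roi"],
            p_thresh=d["p_thresh"],
            positive_edges=np.asarray(d["positive_edges"], int),
            negative_edges=np.asarray(d["negative_edges"], int),
            coefficients={k: np.asarray(v) for k, v in d["coefficients"].items()},
            covariate_names=d["covariate_names"],
            seed=d["seed"],
            scheme=d["scheme"],
        )


@dataclass
class PredictionOutcome:
    r: dict[str, float]
    p: dict[str, float] = field(default_factory=dict)
    per_repeat_r: dict[str, np.ndarray] = field(default_factory=dict)
    predicted: dict[str, np.ndarray] = field(default_factory=dict)
    observed: Optional[np.ndarray] = None


@dataclass
class CVResult:
    outcome: PredictionOutcome
    consensus_positive: np.ndarray
    consensus_negative: np.ndarray
    repeat_consensus_positive: np.ndarray
    repeat_consensus_negative: np.ndarray
    fold_fraction_positive: np.ndarray
    fold_fraction_negative: np.ndarray
    scheme: str
    n_folds_total: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def _folds_kfold(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _folds_sites(site: np.ndarray) -> tuple[list[np.ndarray], list]:
    levels = sorted(pd.unique(site))
    return [np.flatnonzero(site == lev) for lev in levels], levels


def _run_one_cv(
    X: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    folds: Sequence[np.ndarray],
    p_thresh: float,
    refit_covariates: bool,
    pos_counts: Optional[np.ndarray] = None,
    neg_counts: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """One pass over a fold partition; returns out-of-fold predictions."""
    n = len(y)
    preds = {net: np.full(n, np.nan) for net in NETWORKS}
    all_idx = np.arange(n)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=False)
        stats_f = edge_partial_correlations(X[train_idx], y[train_idx], C[train_idx])
        pos, neg = select_edges(stats_f, p_thresh)
        if pos_counts is not None:
            pos_counts[pos.edges] += 1
            neg_counts[neg.edges] += 1
        masks = {
            "positive": (pos, None),
            "negative": (neg, None),
            "combined": (pos, neg),
        }
        for net, (m, m2) in masks.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s_tr = network_strength(X[train_idx], m, m2)
                s_te = network_strength(X[test_idx], m, m2)
            if np.std(s_tr) == 0:
                preds[net][test_idx] = y[train_idx].mean()
                continue
            pred, _ = fit_predict_linear(
                s_tr, C[train_idx], y[train_idx], s_te, C[test_idx],
                refit_covariates=refit_covariates,
            )
            preds[net][test_idx] = pred
    return preds


def run_cv(
    edges: CohortEdgeSet,
    phenotype: np.ndarray,
    covariates: Optional[pd.DataFrame],
    scheme: Literal["kfold", "leave_site_out"] = "kfold",
    k: int = 10,
    n_repeats: int = 50,
    p_thresh: float = DEFAULT_P_THRESH,
    seed: Optional[int] = 0,
    refit_covariates: bool = False,
) -> CVResult:
    """Repeated k-fold or leave-site-out CPM cross-validation.

    Feature selection and model fitting happen strictly inside training
    folds. Reported r per network is the mean over repeats of the
    predicted-vs-observed Pearson correlation (leave-site-out has a single
    deterministic partition, hence one repeat). Consensus masks are edges
    selected in >= 95% of all folds; the repeat-level consensus keeps edges
    selected in >= 95% of folds within at least 48 of 50 repeats.
    """
    y = np.asarray(phenotype, dtype=float)
    X = edges.X
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("phenotype length != number of subjects")
    if scheme == "leave_site_out":
        if covariates is None or "site" not in covariates.columns:
            raise ValueError("leave_site_out requires a 'site' covariate column")
        C, _ = _cov_design(covariates, n, include_site=False)
        folds, levels = _folds_sites(covariates["site"].to_numpy())
        for lev, f in zip(levels, folds):
            if n - len(f) <= C.shape[1] + 3:
                raise DegenerateInputError(
                    f"training set excluding site {lev!r} too small"
                )
            if len(f) < 3:
                raise DegenerateInputError(f"site {lev!r} has fewer than 3 subjects")
        repeats = [folds]
    else:
        C, _ = _cov_design(covariates, n, include_site=True)
        rng = np.random.default_rng(seed)
        repeats = [_folds_kfold(n, k, rng) for _ in range(n_repeats)]

    n_edges = X.shape[1]
    pos_counts = np.zeros(n_edges)
    neg_counts = np.zeros(n_edges)
    repeat_pos_hits = np.zeros(n_edges)
    repeat_neg_hits = np.zeros(n_edges)
    per_repeat = {net: [] for net in NETWORKS}
    last_preds: dict[str, np.ndarray] = {}
    n_folds_total = 0
    for folds in repeats:
        rp = np.zeros(n_edges)
        rn = np.zeros(n_edges)
        preds = _run_one_cv(X, y, C, folds, p_thresh, refit_covariates, rp, rn)
        pos_counts += rp
        neg_counts += rn
        n_folds = len(folds)
        repeat_pos_hits += rp >= CONSENSUS_FRACTION * n_folds
        repeat_neg_hits += rn >= CONSENSUS_FRACTION * n_folds
        n_folds_total += n_folds
        for net in NETWORKS:
            per_repeat[net].append(_pearson(preds[net], y))
        last_preds = preds
    n_repeats_eff = len(repeats)
    outcome = PredictionOutcome(
        r={net: float(np.mean(per_repeat[net])) for net in NETWORKS},
        per_repeat_r={net: np.asarray(per_repeat[net]) for net in NETWORKS},
        predicted=last_preds,
        observed=y,
    )
    frac_pos = pos_counts / n_folds_total
    frac_neg = neg_counts / n_folds_total
    repeat_rule = int(np.ceil(CONSENSUS_FRACTION * n_repeats_eff))  # 48 of 50
    return CVResult(
        outcome=outcome,
        consensus_positive=np.flatnonzero(frac_pos >= CONSENSUS_FRACTION),
        consensus_negative=np.flatnonzero(frac_neg >= CONSENSUS_FRACTION),
        repeat_consensus_positive=np.flatnonzero(repeat_pos_hits >= repeat_rule),
        repeat_consensus_negative=np.flatnonzero(repeat_neg_hits >= repeat_rule),
        fold_fraction_positive=frac_pos,
        fold_fraction_negative=frac_neg,
        scheme=scheme,
        n_folds_total=n_folds_total,
    )


def train_full_model(
    edges: CohortEdgeSet,
    phenotype: np.ndarray,
    covariates: Optional[pd.DataFrame],
    p_thresh: float = DEFAULT_P_THRESH,
    seed: Optional[int] = None,
) -> CPMModel:
    """Fit masks and linear coefficients on the full sample (for transfer)."""
    y = np.asarray(phenotype, dtype=float)
    C, cnames = _cov_design(covariates, len(y), include_site=True)
    est = edge_partial_correlations(edges.X, y, C)
    pos, neg = select_edges(est, p_thresh)
    coefficients = {}
    for net, (m, m2) in {
        "positive": (pos, None),
        "negative": (neg, None),
        "combined": (pos, neg),
    }.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = network_strength(edges.X, m, m2)
        _, beta = fit_predict_linear(s, C, y, s, C)
        coefficients[net] = beta
    return CPMModel(
        n_roi=edges.n_roi,
        p_thresh=p_thresh,
        positive_edges=pos.edges,
        negative_edges=neg.edges,
        coefficients=coefficients,
        covariate_names=cnames,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Permutation inference


def permutation_test(
    edges: CohortEdgeSet,
    phenotype: np.ndarray,
    covariates: Optional[pd.DataFrame],
    scheme: Literal["kfold", "leave_site_out"] = "kfold",
    k: int = 10,
    n_repeats: int = 1,
    p_thresh: float = DEFAULT_P_THRESH,
    n_perm: int = 1000,
    seed: Optional[int] = 0,
) -> PredictionOutcome:
    """Permutation p-values for CPM predictive performance.

    The phenotype is shuffled against the connectomes and the whole CV
    pipeline re-run per permutation; p = (1 + #{null r >= observed r}) /
    (n_perm + 1), one-sided since predictive skill is directional.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)

    def run(yv: np.ndarray, cv_seed: int) -> dict[str, float]:
        res = run_cv(edges, yv, covariates, scheme=scheme, k=k,
                     n_repeats=n_repeats, p_thresh=p_thresh, seed=cv_seed)
        return res.outcome.r

    observed = run(y, int(rng.integers(2**31 - 1)))
    null = {net: np.empty(n_perm) for net in NETWORKS}
    for b in range(n_perm):
        yp = rng.permutation(y)
        rb = run(yp, int(rng.integers(2**31 - 1)))
        for net in NETWORKS:
            null[net][b] = rb[net]
    pvals = {
        net: float((1 + np.sum(null[net] >= observed[net])) / (n_perm + 1))
        for net in NETWORKS
    }
    out = PredictionOutcome(r=observed, p=pvals)
    out.per_repeat_r = {net: null[net] for net in NETWORKS}  # null distribution
    return out


def apply_model_across(
    model: CPMModel,
    edges: CohortEdgeSet,
    covariates: Optional[pd.DataFrame],
    phenotype: np.ndarray,
    mode: Literal["transfer", "residual_correlation"] = "transfer",
    n_perm: int = 1000,
    seed: Optional[int] = 0,
) -> PredictionOutcome:
    """Apply a frozen model to another wave or an external cohort.

    ``transfer``: strengths from the frozen masks are pushed through the
    frozen linear coefficients (target-wave covariate values, frozen
    covariate slopes); r = Pearson(predicted, observed), with p from
    shuffling the predicted values n_perm times. ``residual_correlation``:
    network strength is residualized on the covariates and correlated with
    the observed phenotype directly (external-subgroup variant).
    """
    if edges.n_roi != model.n_roi:
        raise ValueError(
            f"atlas mismatch: model has {model.n_roi} ROIs, data {edges.n_roi}"
        )
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    C, cnames = _cov_design(covariates, len(y), include_site=True)
    masks = {
        "positive": (model.positive_edges, None),
        "negative": (model.negative_edges, None),
        "combined": (model.positive_edges, model.negative_edges),
    }
    r_out, p_out, preds = {}, {}, {}
    for net, (m, m2) in masks.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = network_strength(edges.X, np.asarray(m, int),
                                 None if m2 is None else np.asarray(m2, int))
        if mode == "transfer":
            beta = model.coefficients[net]
            if cnames != model.covariate_names:
                raise ValueError(
                    "target covariate columns differ from the trained model: "
                    f"{cnames} vs {model.covariate_names}"
                )
            Xte = np.hstack([np.ones((len(y), 1)), s[:, None], C])
            pred = Xte @ beta
        elif mode == "residual_correlation":
            pred = _residualize(s[:, None], C)[:, 0]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        obs_r = _pearson(pred, y)
        null = np.array(
            [_pearson(rng.permutation(pred), y) for _ in range(n_perm)]
        )
        r_out[net] = obs_r
        p_out[net] = float((1 + np.sum(null >= obs_r)) / (n_perm + 1))
        preds[net] = pred
    return PredictionOutcome(r=r_out, p=p_out, predicted=preds, observed=y)
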
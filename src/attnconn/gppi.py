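"""Generalized psychophysiological interaction (gPPI) connectivity.

For every ordered pair of atlas regions the seed time series is regressed on
the other region's series (the physiological regressor), HRF-convolved task
regressors for the stop-signal conditions, PPI interaction terms formed at
the neural level (deconvolve the physiological series, gate it by the
condition boxcar, reconvolve with the HRF), a 36-column nuisance block, and
a discrete-cosine high-pass set (128 s cutoff). Two condition models are
supported:

* ``go_trials`` — three task regressors (go, successful stop, failed stop);
  the edge value is the PPI(go) coefficient (8 model coefficients incl.
  intercept);
* ``successful_stop`` — two task regressors (successful / failed stop, go
  trials serving as implicit baseline); edge value is PPI(successful stop)
  (6 coefficients).

Stacking edge values over seeds x targets gives an asymmetric matrix that is
averaged with its transpose to yield the symmetric per-subject connectome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from attnconn.errors import CollinearityError

ConditionModel = Literal["go_trials", "successful_stop"]

#: Task regressors per condition model, in design-column order.
MODEL_CONDITIONS: dict[str, tuple[str, ...]] = {
    "go_trials": ("stop_success", "stop_fail", "go"),
    "successful_stop": ("stop_success", "stop_fail"),
}
#: Condition whose PPI coefficient is the edge value, per model.
MODEL_PPI_CONDITION: dict[str, str] = {
    "go_trials": "go",
    "successful_stop": "stop_success",
}

BASE_CONFOUNDS = (
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "wm_mean",
    "csf_mean",
    "gm_mean",
)

HIGHPASS_CUTOFF_S = 128.0


# ---------------------------------------------------------------------------
# Containers


@dataclass
class ROITimeSeries:
    """BOLD signal per atlas region: ``data`` is time x n_roi."""

    data: np.ndarray
    tr: float
    subject_id: str = ""
    roi_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be time x n_roi with n_roi >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite samples")
        if self.roi_labels is None:
            self.roi_labels = [f"roi{i:03d}" for i in range(self.data.shape[1])]

    @property
    def n_time(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass
class HRFModel:
    """Canonical double-gamma hemodynamic response sampled at ``dt`` seconds."""

    kernel: np.ndarray
    dt: float
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length: float = 32.0

    def at_tr(self, tr: float) -> np.ndarray:
        """Kernel resampled on the acquisition grid (t = 0, tr, 2*tr, ...)."""
        step = int(round(tr / self.dt))
        if step < 1 or abs(step * self.dt - tr) > 1e-9:
            t = np.arange(0.0, self.length, tr)
            return np.interp(t, np.arange(len(self.kernel)) * self.dt, self.kernel)
        return self.kernel[::step]


@dataclass
class GPPIPairFit:
    """Model-block coefficients of one seed/target GLM."""

    coefficients: np.ndarray
    coefficient_names: list[str]
    ppi_edge_value: float
    ppi_se: float
    residual_variance: float
    model: str


@dataclass
class GPPIMatrix:
    """Symmetric zero-diagonal ROI x ROI task-modulated connectivity."""

    matrix: np.ndarray
    condition_model: ConditionModel
    subject_id: str = ""
    roi_labels: Optional[Sequence[str]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T, atol=0, rtol=0):
            raise ValueError("matrix must be exactly symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix contains non-finite entries")
        self.matrix = m


# ---------------------------------------------------------------------------
# HRF and design construction


def canonical_hrf(tr: float, oversampling: int = 16) -> HRFModel:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s, 1:6 ratio).

    Sampled at ``tr / oversampling`` over 32 s and scaled to unit peak. The
    kernel is zero at t=0 and peaks between 4 and 8 s.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    model = HRFModel(kernel=np.empty(0), dt=tr / oversampling)
    t = np.arange(0.0, model.length, model.dt)
    peak = gamma_dist.pdf(t, model.peak_delay / model.peak_dispersion,
                          scale=model.peak_dispersion)
    under = gamma_dist.pdf(t, model.undershoot_delay / model.undershoot_dispersion,
                           scale=model.undershoot_dispersion)
    kernel = peak - under / model.peak_undershoot_ratio
    model.kernel = kernel / kernel.max()
    return model


def condition_boxcar(
    events: pd.DataFrame, condition: str, n_time: int, tr: float, dt: float
) -> np.ndarray:
    """Unit boxcar for one condition on the oversampled grid."""
    n_fine = int(round(n_time * tr / dt))
    box = np.zeros(n_fine)
    sel = events[events["trial_type"] == condition]
    for onset, duration in zip(sel["onset"], sel["duration"]):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + duration) / dt)))
        box[i0 : min(i1, n_fine)] = 1.0
    return box


def _convolved_regressor(box: np.ndarray, hrf: HRFModel, n_time: int,
                         oversampling: int) -> np.ndarray:
    conv = np.convolve(box, hrf.kernel)[: len(box)]
    return conv[::oversampling][:n_time] * hrf.dt


def task_regressors(
    events: pd.DataFrame,
    n_time: int,
    tr: float,
    model: ConditionModel,
    hrf: Optional[HRFModel] = None,
    oversampling: int = 16,
) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved condition boxcars, downsampled to the TR grid."""
    hrf = hrf or canonical_hrf(tr, oversampling)
    conds = MODEL_CONDITIONS[model]
    cols = [
        _convolved_regressor(
            condition_boxcar(events, c, n_time, tr, hrf.dt), hrf, n_time, oversampling
        )
        for c in conds
    ]
    return np.column_stack(cols), [f"psycho_{c}" for c in conds]


def expand_confounds(base: pd.DataFrame | np.ndarray) -> np.ndarray:
    """9 base signals -> 36 nuisance columns.

    The block is [9 base, 9 backward-difference derivatives (first sample 0),
    squares of those 18]; motion (3 translations, 3 rotations) plus mean
    white-matter, CSF and grey-matter signals.
    """
    arr = np.asarray(base, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(BASE_CONFOUNDS):
        raise ValueError(
            f"expected {len(BASE_CONFOUNDS)} base confound columns, got "
            f"{arr.shape[1] if arr.ndim == 2 else 'non-2D'}"
        )
    deriv = np.vstack([np.zeros((1, arr.shape[1])), np.diff(arr, axis=0)])
    first18 = np.hstack([arr, deriv])
    return np.hstack([first18, first18**2])


def confound_labels() -> list[str]:
    base = list(BASE_CONFOUNDS)
    deriv = [f"{c}_derivative1" for c in base]
    return base + deriv + [f"{c}_power2" for c in base + deriv]


def dct_highpass_basis(n_time: int, tr: float,
                       cutoff: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift columns for a high-pass cutoff in seconds.

    The number of columns is floor(2 * n_time * tr / cutoff), i.e. every
    cosine with period longer than the cutoff (the constant is excluded; the
    GLM carries its own intercept).
    """
    k_max = int(np.floor(2.0 * n_time * tr / cutoff))
    t = np.arange(n_time)
    cols = [
        np.sqrt(2.0 / n_time) * np.cos(np.pi * (2 * t + 1) * k / (2 * n_time))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_time, 0))


def build_design(
    events: pd.DataFrame,
    confounds: pd.DataFrame | np.ndarray,
    n_time: int,
    tr: float,
    model: ConditionModel,
    hrf: Optional[HRFModel] = None,
) -> tuple[np.ndarray, list[str]]:
    """Task + 36-nuisance + cosine-drift design (no intercept column).

    Raises :class:`CollinearityError` naming near-collinear columns when the
    design (plus intercept) is rank deficient.
    """
    task, task_names = task_regressors(events, n_time, tr, model, hrf)
    nuis = expand_confounds(confounds)
    if nuis.shape[0] != n_time:
        raise ValueError("confound rows must match n_time")
    dct = dct_highpass_basis(n_time, tr)
    X = np.hstack([task, nuis, dct])
    names = task_names + confound_labels() + [
        f"cosine{k:02d}" for k in range(1, dct.shape[1] + 1)
    ]
    _check_rank(np.hstack([np.ones((n_time, 1)), X]), ["intercept"] + names)
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank relative to the rest
        bad = []
        sd = X.std(axis=0)
        for j in range(1, X.shape[1]):
            if sd[j] == 0:
                bad.append(names[j])
        if not bad:
            q, r = np.linalg.qr(X)
            diag = np.abs(np.diag(r))
            thresh = diag.max() * 1e-10
            bad = [names[j] for j in range(X.shape[1]) if diag[j] < thresh]
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}"
        )


# ---------------------------------------------------------------------------
# Deconvolution


class Deconvolver:
    """Ridge-regularized cosine-basis inverse of HRF convolution.

    The neural signal is represented on a full discrete-cosine basis at the
    TR grid; the ridge weight is chosen by generalized cross-validation over
    a log-spaced grid. The expensive SVD depends only on (n_time, tr, HRF)
    and is cached, so deconvolving many ROI series of one run is cheap.
    """

    def __init__(self, n_time: int, tr: float, hrf: HRFModel,
                 lambdas: Optional[np.ndarray] = None):
        self.n_time = n_time
        self.tr = tr
        kernel_tr = hrf.at_tr(tr) * tr
        first_col = np.zeros(n_time)
        k = min(len(kernel_tr), n_time)
        first_col[:k] = kernel_tr[:k]
        H = np.zeros((n_time, n_time))
        for i in range(n_time):
            H[i, : i + 1] = first_col[: i + 1][::-1]
        # orthonormal DCT-II basis (includes the constant)
        t = np.arange(n_time)
        B = np.empty((n_time, n_time))
        B[:, 0] = 1.0 / np.sqrt(n_time)
        for j in range(1, n_time):
            B[:, j] = np.sqrt(2.0 / n_time) * np.cos(
                np.pi * (2 * t + 1) * j / (2 * n_time)
            )
        self.B = B
        U, s, Vt = np.linalg.svd(H @ B, full_matrices=False)
        self.U, self.s, self.Vt = U, s, Vt
        self.lambdas = (
            lambdas if lambdas is not None else np.logspace(-12, 2, 29)
        )

    def __call__(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n_time:
            raise ValueError("series length mismatch")
        if not np.any(y):
            return np.zeros_like(y)
        uy = self.U.T @ y
        n = self.n_time
        best = (np.inf, None)
        for lam in self.lambdas:
            shrink = self.s**2 / (self.s**2 + lam)
            rss = float(np.sum(((1 - shrink) * uy) ** 2))
            df = float(np.sum(shrink))
            denom = max(1.0 - df / n, 1e-12) ** 2
            gcv = rss / n / denom
            if gcv < best[0]:
                best = (gcv, lam)
        lam = best[1]
        coef = self.Vt.T @ (self.s / (self.s**2 + lam) * uy)
        return self.B @ coef

    def reconvolve(self, neural: np.ndarray) -> np.ndarray:
        coef = self.B.T @ neural
        return self.U @ (self.s * (self.Vt @ coef))

    def convolve(self, neural: np.ndarray) -> np.ndarray:
        """Forward convolution with the TR-grid kernel (exact operator)."""
        return self.reconvolve(neural)


def deconvolve_to_neural(bold: np.ndarray, hrf: HRFModel, tr: float) -> np.ndarray:
    """One-shot neural-level estimate for a single BOLD series."""
    return Deconvolver(len(bold), tr, hrf)(bold)


# ---------------------------------------------------------------------------
# gPPI GLMs


def _ppi_terms(
    neural: np.ndarray,
    events: pd.DataFrame,
    dec: Deconvolver,
    tr: float,
    model: ConditionModel,
) -> tuple[np.ndarray, list[str]]:
    """PPI regressors: neural series gated by condition boxcars, reconvolved."""
    n_time = len(neural)
    cols, names = [], []
    for cond in MODEL_CONDITIONS[model]:
        fine = condition_boxcar(events, cond, n_time, tr, tr)  # TR-grid boxcar
        cols.append(dec.convolve(neural * fine[:n_time]))
        names.append(f"ppi_{cond}")
    return np.column_stack(cols), names


def _common_design(events, confounds, n_time, tr, model, hrf):
    X, names = build_design(events, confounds, n_time, tr, model, hrf)
    return (
        np.hstack([np.ones((n_time, 1)), X]),
        ["intercept"] + names,
    )


def fit_gppi_pair(
    seed: np.ndarray,
    target: np.ndarray,
    events: pd.DataFrame,
    confounds: pd.DataFrame | np.ndarray,
    tr: float,
    model: ConditionModel = "go_trials",
    hrf: Optional[HRFModel] = None,
    deconvolver: Optional[Deconvolver] = None,
) -> GPPIPairFit:
    """OLS fit of one seed series on a target's physiological + PPI terms.

    The returned ``coefficients`` are the model block only (intercept,
    physiological, task, PPI), 8 entries for the go-trials model and 6 for
    the successful-stop model; nuisance and drift coefficients are estimated
    jointly but not reported.
    """
    seed = np.asarray(seed, dtype=float)
    target = np.asarray(target, dtype=float)
    if seed.shape != target.shape:
        raise ValueError("seed and target must have the same length")
    if np.std(target) == 0:
        raise CollinearityError("target series is constant")
    n_time = len(seed)
    hrf = hrf or canonical_hrf(tr)
    dec = deconvolver or Deconvolver(n_time, tr, hrf)
    C, cnames = _common_design(events, confounds, n_time, tr, model, hrf)
    neural = dec(target)
    ppi, pnames = _ppi_terms(neural, events, dec, tr, model)
    n_task = len(MODEL_CONDITIONS[model])
    # column order: intercept, physio, psycho..., ppi..., nuisance/drift
    X = np.hstack([C[:, :1], target[:, None], C[:, 1 : 1 + n_task], ppi,
                   C[:, 1 + n_task :]])
    names = (
        ["intercept", "physio"] + cnames[1 : 1 + n_task] + pnames
        + cnames[1 + n_task :]
    )
    beta, _, rank, _ = np.linalg.lstsq(X, seed, rcond=None)
    if rank < X.shape[1]:
        raise CollinearityError("pair design is rank deficient")
    resid = seed - X @ beta
    dof = max(n_time - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    ppi_idx = names.index(f"ppi_{MODEL_PPI_CONDITION[model]}")
    n_model = 2 + 2 * n_task
    return GPPIPairFit(
        coefficients=beta[:n_model].copy(),
        coefficient_names=names[:n_model],
        ppi_edge_value=float(beta[ppi_idx]),
        ppi_se=float(np.sqrt(sigma2 * XtX_inv[ppi_idx, ppi_idx])),
        residual_variance=sigma2,
        model=model,
    )


def symmetrize(matrix: np.ndarray) -> np.ndarray:
    """(M + M^T)/2 with the diagonal forced to zero."""
    m = (matrix + matrix.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def build_gppi_matrix(
    ts: ROITimeSeries,
    events: pd.DataFrame,
    confounds: pd.DataFrame | np.ndarray,
    model: ConditionModel = "go_trials",
    hrf: Optional[HRFModel] = None,
) -> GPPIMatrix:
    """Symmetric per-subject gPPI connectome for one condition model.

    Entry (i, j) before symmetrization is the PPI coefficient with ROI i as
    seed (response) and ROI j as the physiological/PPI source; all seeds
    sharing a source are fitted in one least-squares solve, so the whole
    matrix costs n_roi solves rather than n_roi^2.
    """
    n_time, n_roi = ts.n_time, ts.n_roi
    hrf = hrf or canonical_hrf(ts.tr)
    dec = Deconvolver(n_time, ts.tr, hrf)
    C, _ = _common_design(events, confounds, n_time, ts.tr, model, hrf)
    n_task = len(MODEL_CONDITIONS[model])
    ppi_cond_idx = MODEL_CONDITIONS[model].index(MODEL_PPI_CONDITION[model])
    Y = ts.data
    M = np.zeros((n_roi, n_roi))
    for j in range(n_roi):
        target = Y[:, j]
        if np.std(target) == 0:
            raise CollinearityError(f"ROI {ts.roi_labels[j]} is constant")
        neural = dec(target)
        ppi, _ = _ppi_terms(neural, events, dec, ts.tr, model)
        X = np.hstack([C[:, :1], target[:, None], C[:, 1 : 1 + n_task], ppi,
                       C[:, 1 + n_task :]])
        beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        if rank < X.shape[1]:
            raise CollinearityError(
                f"rank-deficient design for source ROI {ts.roi_labels[j]}"
            )
        M[:, j] = beta[2 + n_task + ppi_cond_idx]
    return GPPIMatrix(
        matrix=symmetrize(M),
        condition_model=model,
        subject_id=ts.subject_id,
        roi_labels=list(ts.roi_labels),
        meta={"tr": ts.tr, "n_time": n_time, "hrf_peak_delay": hrf.peak_delay},
    )


# ---------------------------------------------------------------------------
# IO


def read_timeseries_tsv(path, tr: float, subject_id: str = "") -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(df.to_numpy(float), tr=tr, subject_id=subject_id,
                         roi_labels=list(df.columns))


def read_events_tsv(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "trial_type"} - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    return events


def read_confounds_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(BASE_CONFOUNDS) - set(df.columns)
    if missing:
        raise ValueError(f"confounds table missing columns {sorted(missing)}")
    return df[list(BASE_CONFOUNDS)]


def save_matrices_h5(path, matrices: Sequence[GPPIMatrix]) -> None:
    """Store per-subject matrices, grouped by condition model."""
    with h5py.File(path, "w") as f:
        for gm in matrices:
            grp = f.require_group(gm.condition_model)
            d = grp.create_dataset(gm.subject_id or f"subject{len(grp)}",
                                   data=gm.matrix)
            for k, v in gm.meta.items():
                d.attrs[k] = v
            if gm.roi_labels is not None:
                d.attrs["roi_labels"] = [str(x) for x in gm.roi_labels]


def load_matrices_h5(path, condition_model: ConditionModel) -> list[GPPIMatrix]:
    out = []
    with h5py.File(path, "r") as f:
        grp = f[condition_model]
        for sid in sorted(grp):
            d = grp[sid]
            labels = d.attrs.get("roi_labels")
            out.append(
                GPPIMatrix(
                    matrix=d[()],
                    condition_model=condition_model,
                    subject_id=sid,
                    roi_labels=None if labels is None else [str(x) for x in labels],
                    meta={k: v for k, v in d.attrs.items() if k != "roi_labels"},
                )
            )
    return out
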
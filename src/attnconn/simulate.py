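"""Synthetic-cohort generators for every stage of the pipeline.

Nothing here touches real data: the generators emit stop-signal trial
tables, ROI BOLD time series with planted condition-gated couplings,
three-wave connectome cohorts with planted predictive edge networks, and
substance-use trajectories with known cross-lagged couplings — each
alongside a ground-truth record sufficient to compute theoretical recovery
ceilings. Every generator is a pure function of its arguments and an
explicit seed/Generator, so two runs agree bit for bit.

Default cohort conditions emulate the longitudinal study design the
pipeline targets: three waves (ages 14/19/23), eight acquisition sites,
ICV means/SDs calibrated per wave (0.234/0.038, 0.224/0.051, 0.217/0.052),
adjacent-wave trait stability rho = 0.5, and 20 positive + 20 negative
planted edges at an edge-phenotype correlation of about 0.3. The desk-scale
default is 200 subjects x 60 ROIs so a full CPM run stays in the minutes
range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from attnconn import sst
from attnconn.cpm import CohortEdgeSet, devectorize, network_strength
from attnconn.gppi import (
    Deconvolver,
    GPPIMatrix,
    HRFModel,
    BASE_CONFOUNDS,
    canonical_hrf,
    condition_boxcar,
)

# ---------------------------------------------------------------------------
# Stop-signal task


@dataclass
class StaircaseResult:
    successes: np.ndarray  # bool per stop trial
    ssds: np.ndarray       # SSD presented on each stop trial (ms)
    go_finish: np.ndarray  # underlying go-process finish times (ms)

    @property
    def success_rate(self) -> float:
        return float(np.mean(self.successes))


def simulate_staircase(
    n_stop: int,
    mu_go: float = 500.0,
    sd_go: float = 100.0,
    ssrt: float = 200.0,
    rng: np.random.Generator | int | None = 0,
    ssd_start: float = 300.0,
    hard_clamp_state: bool = False,
) -> StaircaseResult:
    """Independent-race stop trials under the +/-50 ms tracking rule.

    The go process finishes at Normal(mu_go, sd_go) (truncated positive);
    inhibition succeeds iff the finish time exceeds SSD + SSRT. The
    staircase steps up 50 ms after a successful stop and down 50 ms after a
    failed one, and the presented SSD is clamped to the 250-900 ms grid.

    By default the staircase *state* is tracked without bounds and only the
    presented delay is clamped: up- and down-moves then balance exactly in
    the long run, so the success rate converges to the designed 50% even
    when the race equilibrium (mu_go - ssrt) sits next to the grid floor.
    ``hard_clamp_state=True`` clamps the state itself, in which case
    failures at the floor become self-loops and the long-run success rate
    drops below one half whenever the equilibrium is within a step or two
    of a bound.
    """
    if not (mu_go > ssrt > 0):
        raise ValueError("require mu_go > ssrt > 0 for an admissible race")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    def clamp(v: float) -> float:
        return float(np.clip(v, sst.SSD_MIN_MS, sst.SSD_MAX_MS))

    state = clamp(round(ssd_start / sst.SSD_STEP_MS) * sst.SSD_STEP_MS)
    finishes = np.empty(n_stop)
    ssds = np.empty(n_stop)
    succ = np.empty(n_stop, dtype=bool)
    for i in range(n_stop):
        finish = rng.normal(mu_go, sd_go)
        while finish <= 0:
            finish = rng.normal(mu_go, sd_go)
        ssd = clamp(state)
        ssds[i] = ssd
        success = finish > ssd + ssrt
        succ[i] = success
        finishes[i] = finish
        state += sst.SSD_STEP_MS if success else -sst.SSD_STEP_MS
        if hard_clamp_state:
            state = clamp(state)
    return StaircaseResult(successes=succ, ssds=ssds, go_finish=finishes)


def simulate_sst_trials(
    rng: np.random.Generator | int | None = 0,
    n_go: int = 400,
    n_stop: int = 80,
    mu_go: float = 500.0,
    sd_go: float = 100.0,
    ssrt: float = 200.0,
    p_omission: float = 0.044,
    p_choice_error: float = 0.047,
    p_late: float = 0.01,
    trial_spacing_s: float = 2.0,
) -> list[sst.TrialRecord]:
    """One subject's full SST run (400 go + 80 stop trials by default).

    Stop trials are spaced 3-7 go trials apart as in the acquisition
    protocol; go RTs are truncated-normal, with configurable omission,
    choice-error, and late rates matched to adolescent cohort tables.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    race = simulate_staircase(n_stop, mu_go, sd_go, ssrt, rng)
    # interleave: 3-7 go trials between successive stop trials
    order: list[str] = []
    go_left, stop_left = n_go, n_stop
    while go_left > 0 or stop_left > 0:
        run = int(rng.integers(3, 8))
        take = min(run, go_left)
        order += ["go"] * take
        go_left -= take
        if stop_left > 0:
            order.append("stop")
            stop_left -= 1
    trials: list[sst.TrialRecord] = []
    stop_i = 0
    for idx, ttype in enumerate(order):
        onset = idx * trial_spacing_s
        side = "left" if rng.random() < 0.5 else "right"
        if ttype == "go":
            u = rng.random()
            if u < p_omission:
                trials.append(sst.TrialRecord(idx, "go", onset, side))
                continue
            rt = rng.normal(mu_go, sd_go)
            while rt <= 0:
                rt = rng.normal(mu_go, sd_go)
            wrong = u < p_omission + p_choice_error
            late = (not wrong) and rng.random() < p_late
            trials.append(
                sst.TrialRecord(
                    idx, "go", onset, side,
                    response=("left" if side == "right" else "right") if wrong else side,
                    rt=float(rt), late_flag=late,
                )
            )
        else:
            success = race.successes[stop_i]
            trials.append(
                sst.TrialRecord(
                    idx, "stop", onset, side,
                    response="none" if success else side,
                    rt=None if success else float(race.go_finish[stop_i]),
                    ssd=float(race.ssds[stop_i]),
                )
            )
            stop_i += 1
    return trials


def trials_to_events(trials: Sequence[sst.TrialRecord],
                     go_duration: float = 1.0,
                     stop_duration: float = 1.0) -> pd.DataFrame:
    """BIDS-style events table with go / stop_success / stop_fail conditions."""
    rows = []
    for t in trials:
        if t.trial_type == "go":
            cond, dur = "go", go_duration
        else:
            cond = "stop_success" if not t.responded else "stop_fail"
            dur = stop_duration
        rows.append({"onset": t.onset, "duration": dur, "trial_type": cond})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gPPI forward model


def simulate_confounds(n_time: int, rng: np.random.Generator) -> pd.DataFrame:
    """Smooth random-walk motion and tissue-mean base signals (9 columns)."""
    steps = rng.normal(0, 0.02, size=(n_time, len(BASE_CONFOUNDS)))
    return pd.DataFrame(np.cumsum(steps, axis=0), columns=list(BASE_CONFOUNDS))


def simulate_ppi_timeseries(
    n_rois: int,
    events: pd.DataFrame,
    tr: float = 2.2,
    n_time: int = 300,
    couplings: Optional[Mapping[tuple[int, int, str], float]] = None,
    physio_couplings: Optional[Mapping[tuple[int, int], float]] = None,
    intrinsic_sd: float | Sequence[float] = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = 0,
    hrf: Optional[HRFModel] = None,
    n_basis: Optional[int] = None,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """ROI BOLD with planted condition-gated interactions.

    Each region starts from an intrinsic low-frequency neural signal
    convolved with the HRF plus white measurement noise. ``couplings`` maps
    (receiver ROI, source ROI, condition) -> coefficient: the receiver then
    gains coefficient x conv(deconv(observed source) x condition boxcar) —
    the exact PPI structure the pair GLM assumes, so the interaction
    coefficient is identified without attenuation and, when the receiver
    carries no intrinsic signal or noise of its own (``intrinsic_sd`` may
    be a per-ROI sequence), recovered to numerical precision.
    ``physio_couplings`` adds plain (condition-independent) source-to-
    receiver terms.

    Returns (bold time x n_rois, confounds table, ground-truth dict).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    hrf = hrf or canonical_hrf(tr)
    dec = Deconvolver(n_time, tr, hrf)
    k = n_basis or max(8, n_time // 4)
    coefs = rng.normal(0, 1.0, size=(k, n_rois))
    neural = dec.B[:, 1 : k + 1] @ coefs
    boxes = {
        c: condition_boxcar(events, c, n_time, tr, tr)[:n_time]
        for c in ("go", "stop_success", "stop_fail")
    }
    intr = np.broadcast_to(np.asarray(intrinsic_sd, dtype=float), (n_rois,))
    bold = intr * np.column_stack(
        [dec.convolve(neural[:, j]) for j in range(n_rois)]
    )
    if noise_sd > 0:
        bold = bold + rng.normal(0, noise_sd, size=bold.shape)
    # coupling contributions are built from the observed source series so
    # the planted coefficients match the pair-GLM regressors exactly
    source_rois = {src for (_, src, _) in (couplings or {})} | {
        src for (_, src) in (physio_couplings or {})
    }
    src_neural = {s: dec(bold[:, s]) for s in source_rois}
    for (recv, src), beta in (physio_couplings or {}).items():
        bold[:, recv] = bold[:, recv] + beta * bold[:, src]
    for (recv, src, cond), kappa in (couplings or {}).items():
        bold[:, recv] = bold[:, recv] + kappa * dec.convolve(
            src_neural[src] * boxes[cond]
        )
    confounds = simulate_confounds(n_time, rng)
    truth = {"couplings": dict(couplings or {}), "noise_sd": noise_sd,
             "intrinsic_sd": intrinsic_sd, "n_basis": k}
    return bold, confounds, truth


# ---------------------------------------------------------------------------
# Connectome cohort


#: Per-wave ICV calibration (mean, SD), matching the adolescent cohort table.
ICV_CALIBRATION = {1: (0.234, 0.038), 2: (0.224, 0.051), 3: (0.217, 0.052)}
AGE_CALIBRATION = {1: (14.4, 0.4), 2: (19.0, 0.7), 3: (22.6, 0.7)}
FD_CALIBRATION = {1: (0.28, 0.32), 2: (0.18, 0.17), 3: (0.18, 0.12)}


@dataclass
class CohortConfig:
    """Generative conditions for the three-wave connectome cohort."""

    n_subjects: int = 200
    n_rois: int = 60
    n_waves: int = 3
    n_sites: int = 8
    seed: int = 0
    n_positive_edges: int = 20
    n_negative_edges: int = 20
    edge_phenotype_r: float = 0.3
    trait_phenotype_r: float = 0.8
    rank_stability: float = 0.5
    site_edge_sd: float = 0.2
    icv_calibration: dict = field(default_factory=lambda: dict(ICV_CALIBRATION))

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["icv_calibration"] = {int(k): list(v) for k, v in
                                self.icv_calibration.items()}
        return d


@dataclass
class CohortData:
    config: CohortConfig
    edges: dict[int, CohortEdgeSet]
    phenotype: pd.DataFrame          # subjects x waves, ICV
    covariates: dict[int, pd.DataFrame]
    ground_truth: dict

    @property
    def subject_ids(self) -> list[str]:
        return list(self.phenotype.index)

    def matrices(self, wave: int,
                 condition_model: str = "go_trials") -> list[GPPIMatrix]:
        es = self.edges[wave]
        return [
            GPPIMatrix(
                matrix=devectorize(es.X[i], es.n_roi),
                condition_model=condition_model,
                subject_id=sid,
            )
            for i, sid in enumerate(es.subject_ids)
        ]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_connectome_cohort(config: Optional[CohortConfig] = None,
                               **overrides) -> CohortData:
    """Three-wave cohort of connectome edges, ICV phenotype, covariates.

    A latent attention trait per subject evolves across waves as an AR(1)
    process with adjacent-wave correlation ``rank_stability``. Planted
    positive/negative edges load on the trait with a loading set so the
    marginal edge-ICV correlation is ``edge_phenotype_r``; all edges carry
    per-site offsets and unit noise. ICV is an affine transform of a noisy
    trait readout calibrated to the per-wave (mean, SD) targets.
    """
    config = config or CohortConfig()
    if overrides:
        config = CohortConfig(**{**config.__dict__, **overrides})
    for w, (mu, sd) in config.icv_calibration.items():
        if sd <= 0:
            raise ValueError(f"infeasible ICV calibration at wave {w}: SD {sd}")
    if config.edge_phenotype_r >= config.trait_phenotype_r:
        raise ValueError("edge_phenotype_r must be below trait_phenotype_r")
    rng = np.random.default_rng(config.seed)
    n, n_roi = config.n_subjects, config.n_rois
    n_edges = n_roi * (n_roi - 1) // 2
    n_pos, n_neg = config.n_positive_edges, config.n_negative_edges
    planted = rng.choice(n_edges, size=n_pos + n_neg, replace=False)
    pos_edges = np.sort(planted[:n_pos])
    neg_edges = np.sort(planted[n_pos:])

    rho = config.rank_stability
    traits = np.empty((n, config.n_waves))
    innov = rng.standard_normal((n, config.n_waves))
    traits[:, 0] = innov[:, 0]
    for w in range(1, config.n_waves):
        traits[:, w] = rho * traits[:, w - 1] + np.sqrt(1 - rho**2) * innov[:, w]

    # balanced site assignment (sizes differ by at most 1)
    site = rng.permutation(np.arange(n) % config.n_sites)
    subject_ids = [f"sub{i:04d}" for i in range(n)]
    sex = rng.integers(0, 2, size=n)

    # edge loading from the target marginal edge-phenotype correlation
    r_et = config.edge_phenotype_r / config.trait_phenotype_r
    b = r_et / np.sqrt(1.0 - r_et**2)  # unit residual SD per edge

    edges: dict[int, CohortEdgeSet] = {}
    covs: dict[int, pd.DataFrame] = {}
    phen = pd.DataFrame(index=subject_ids,
                        columns=range(1, config.n_waves + 1), dtype=float)
    ceiling = {}
    r_tp = config.trait_phenotype_r
    for w in range(1, config.n_waves + 1):
        t = traits[:, w - 1]
        X = rng.standard_normal((n, n_edges))
        site_offsets = rng.normal(0, config.site_edge_sd,
                                  size=(config.n_sites, n_edges))
        X += site_offsets[site]
        X[:, pos_edges] += b * t[:, None]
        X[:, neg_edges] -= b * t[:, None]
        mu, sd = config.icv_calibration[w]
        readout = r_tp * t + np.sqrt(1 - r_tp**2) * rng.standard_normal(n)
        icv = mu + sd * readout
        phen[w] = icv
        age_mu, age_sd = AGE_CALIBRATION.get(w, (20.0, 1.0))
        fd_mu, fd_sd = FD_CALIBRATION.get(w, (0.2, 0.1))
        lmu, lsd = _lognormal_params(fd_mu, fd_sd)
        cov = pd.DataFrame(
            {
                "age": rng.normal(age_mu, age_sd, size=n),
                "sex": sex,
                "site": site,
                "mean_fd": rng.lognormal(lmu, lsd, size=n),
            },
            index=subject_ids,
        )
        if w == 1:
            pds = rng.choice([1, 2, 3, 4, 5], size=n,
                             p=[0.05, 0.15, 0.4, 0.3, 0.1])
            cov["pds"] = pds - 3  # mode-centered
        covs[w] = cov
        edges[w] = CohortEdgeSet(X=X, n_roi=n_roi, subject_ids=subject_ids,
                                 wave=str(w))
        s_true = network_strength(X, pos_edges, neg_edges)
        ceiling[w] = _partial_pearson(s_true, icv, site)
    truth = {
        "positive_edges": pos_edges,
        "negative_edges": neg_edges,
        "edge_loading": b,
        "traits": traits,
        "trait_innovations": innov,
        "ceiling_r": ceiling,
    }
    return CohortData(config=config, edges=edges, phenotype=phen,
                      covariates=covs, ground_truth=truth)


def _partial_pearson(x: np.ndarray, y: np.ndarray, site: np.ndarray) -> float:
    """Pearson r between x and y after removing site means from both."""
    dummies = pd.get_dummies(site).to_numpy(float)
    def resid(v):
        beta, _, _, _ = np.linalg.lstsq(dummies, v, rcond=None)
        return v - dummies @ beta
    rx, ry = resid(x), resid(y)
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


# ---------------------------------------------------------------------------
# Substance-use trajectories


#: item -> (factor, log-scale intercept); wave-1 items first six.
TLFB_ITEMS = {
    "alcohol_freq": ("alcohol", 1.2),
    "alcohol_quantity": ("alcohol", 1.0),
    "binge_freq": ("alcohol", 0.4),
    "tobacco_freq": ("cig_cb", 0.8),
    "tobacco_quantity": ("cig_cb", 0.9),
    "cannabis_freq": ("cig_cb", 0.3),
    "cocaine_freq": ("drug", -0.3),
    "ecstasy_freq": ("drug", -0.3),
    "ketamine_freq": ("drug", -0.4),
}
WAVE1_ITEMS = list(TLFB_ITEMS)[:6]


@dataclass
class SubstanceData:
    tlfb: dict[int, pd.DataFrame]
    factor_scores: dict[int, pd.DataFrame]  # true latent factors per wave
    ground_truth: dict


def simulate_substance_trajectories(
    cohort: CohortData,
    gamma1: float = 0.0,
    gamma2: float = 0.12,
    beta_self: float = -0.3,
    factor_loading: float = 1.0,
    item_noise_sd: float = 0.7,
    residual_sd: float = 0.6,
    baseline_corr: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> SubstanceData:
    """TLFB item counts driven by latent factors cross-coupled to attention.

    The cigarette+cannabis factor follows the bivariate latent-change
    generative equations against the cohort's standardized attention trait
    (gamma2: attention -> change in use). A coupled attention series with
    the reverse path gamma1 (use -> change in attention) is built from the
    cohort's stored trait innovations and returned as
    ``ground_truth["attention_series"]``; with gamma1 = 0 (the default) it
    coincides exactly with the traits that generated the cohort's ICV and
    edges, so the whole pipeline stays mutually consistent. Alcohol and
    (waves 2-3) drug factors are uncoupled AR processes. Counts are rounded
    lognormal transforms of the factor scores, giving heavy tails and exact
    zeros.
    """
    rng = np.random.default_rng(
        cohort.config.seed + 1 if rng is None else rng
    ) if not isinstance(rng, np.random.Generator) else rng
    n = len(cohort.subject_ids)
    n_waves = cohort.config.n_waves
    innov = cohort.ground_truth["trait_innovations"]
    rho = cohort.config.rank_stability
    # coupled attention series; identical to the cohort traits when gamma1=0
    a = np.empty((n, n_waves))
    a[:, 0] = innov[:, 0]
    fac = {"cig_cb": np.empty((n, n_waves)), "alcohol": np.empty((n, n_waves)),
           "drug": np.empty((n, n_waves))}
    fac["cig_cb"][:, 0] = baseline_corr * a[:, 0] + np.sqrt(
        1 - baseline_corr**2
    ) * rng.standard_normal(n)
    fac["alcohol"][:, 0] = rng.standard_normal(n)
    fac["drug"][:, 0] = np.zeros(n)
    for w in range(1, n_waves):
        s = fac["cig_cb"][:, w - 1]
        a[:, w] = (
            rho * a[:, w - 1] + gamma1 * s + np.sqrt(1 - rho**2) * innov[:, w]
        )
        fac["cig_cb"][:, w] = (
            s + beta_self * s + gamma2 * a[:, w - 1]
            + residual_sd * rng.standard_normal(n)
        )
        al = fac["alcohol"][:, w - 1]
        fac["alcohol"][:, w] = al + beta_self * al + residual_sd * (
            rng.standard_normal(n)
        )
        fac["drug"][:, w] = 0.2 * fac["cig_cb"][:, w] + np.sqrt(1 - 0.04) * (
            rng.standard_normal(n)
        )
    tlfb = {}
    scores = {}
    ids = cohort.subject_ids
    for w in range(1, n_waves + 1):
        items = WAVE1_ITEMS if w == 1 else list(TLFB_ITEMS)
        cols = {}
        for item in items:
            factor, mu = TLFB_ITEMS[item]
            latent = mu + factor_loading * fac[factor][:, w - 1] + (
                item_noise_sd * rng.standard_normal(n)
            )
            cols[item] = np.clip(np.round(np.exp(latent) - 1.0), 0, None)
        tlfb[w] = pd.DataFrame(cols, index=ids)
        scores[w] = pd.DataFrame(
            {k: fac[k][:, w - 1] for k in ("cig_cb", "alcohol", "drug")},
            index=ids,
        )
    truth = {
        "gamma1": gamma1, "gamma2": gamma2, "beta_self": beta_self,
        "factor_loading": factor_loading, "item_noise_sd": item_noise_sd,
        "attention_series": a,
    }
    return SubstanceData(tlfb=tlfb, factor_scores=scores, ground_truth=truth)


# ---------------------------------------------------------------------------
# Bivariate LCS generative model


def simulate_lcs_dataset(
    n: int = 1000,
    gamma1: float = 0.0,
    gamma2: float = 0.12,
    beta_a: float = -0.3,
    beta_s: float = -0.3,
    baseline_cov: float = 0.3,
    residual_sd: float = 0.6,
    residual_corr: float = 0.1,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Draw a three-wave pair dataset from the LCS generative equations.

    Columns a1..a3 (attention) and s1..s3 (substance); wave-1 scores are
    standard bivariate normal with correlation ``baseline_cov``. The
    defaults put gamma2 at the magnitude reported for attention-to-use
    lagged effects and gamma1 at zero, the asymmetric scenario.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cov0 = np.array([[1.0, baseline_cov], [baseline_cov, 1.0]])
    z = rng.multivariate_normal([0, 0], cov0, size=n)
    a, s = z[:, 0], z[:, 1]
    out = {"a1": a, "s1": s}
    psi = residual_sd**2 * np.array(
        [[1.0, residual_corr], [residual_corr, 1.0]]
    )
    for w in (2, 3):
        e = rng.multivariate_normal([0, 0], psi, size=n)
        a_next = a + beta_a * a + gamma1 * s + e[:, 0]
        s_next = s + beta_s * s + gamma2 * a + e[:, 1]
        out[f"a{w}"], out[f"s{w}"] = a_next, s_next
        a, s = a_next, s_next
    return pd.DataFrame(out)
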
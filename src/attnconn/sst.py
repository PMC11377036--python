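"""Stop-signal-task behavioral metrics and sample-inclusion rules.

The stop signal task (SST) interleaves Go trials (respond left/right to an
arrow) with Stop trials on which a stop signal follows the go stimulus after
a staircase-adjusted stop-signal delay (SSD, 250-900 ms in 50 ms steps).
This module turns trial tables into per-subject summaries:

* ICV — intra-individual coefficient of variation, SD(Go RT) / mean(Go RT),
  the sustained-attention phenotype (lower = steadier responding);
* SSRT — stop-signal reaction time, estimated from the horse-race model by
  the integration method (default) or the mean method;
* go/stop error rates, and the motion + go-error exclusion rules used to
  gate subjects into the connectome analysis.

ICV is computed over correct, on-time Go responses only: omissions have no
RT and choice errors or late responses index lapses rather than ordinary
response-time variability. "Errors on Go trials" for exclusion purposes are
wrong-side responses, omissions, and late responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from attnconn.errors import DegenerateInputError

SSD_MIN_MS = 250.0
SSD_MAX_MS = 900.0
SSD_STEP_MS = 50.0

#: Go error fraction above which a subject is excluded (strict inequality).
GO_ERROR_LIMIT = 0.20
#: Mean framewise displacement (mm) above which a subject is excluded.
MEAN_FD_LIMIT = 0.5


@dataclass(frozen=True)
class TrialRecord:
    """One SST trial.

    ``ssd`` is present iff the trial is a stop trial; ``rt`` is absent when
    no response was made. Times are milliseconds except ``onset`` (seconds).
    """

    trial_index: int
    trial_type: Literal["go", "stop"]
    onset: float
    correct_side: Literal["left", "right"]
    response: Literal["left", "right", "none"] = "none"
    rt: Optional[float] = None
    ssd: Optional[float] = None
    late_flag: bool = False

    def __post_init__(self) -> None:
        if self.trial_type not in ("go", "stop"):
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.rt is not None and self.rt <= 0:
            raise ValueError("rt must be positive when present")
        if (self.ssd is not None) != (self.trial_type == "stop"):
            raise ValueError("ssd must be present iff trial_type='stop'")

    @property
    def responded(self) -> bool:
        return self.response != "none"


@dataclass
class BehavioralSummary:
    """Per-subject SST summary (the usual cohort-table row).

    Percentages are on a 0-100 scale; ``go_error_rate`` is the 0-1 fraction
    used by the exclusion rule (wrong side + omission + late over Go trials).
    """

    icv: float
    mean_go_rt: float
    sd_go_rt: float
    stop_rt: float
    mean_ssd: float
    ssrt: float
    p_omission: float
    p_choice_error: float
    p_commission: float
    n_go: int
    n_stop: int
    go_error_rate: float
    ssrt_reliable: bool = True

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


@dataclass(frozen=True)
class ExclusionDecision:
    include: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def _go_partition(trials: Sequence[TrialRecord]):
    go = [t for t in trials if t.trial_type == "go"]
    omitted = [t for t in go if not t.responded]
    responded = [t for t in go if t.responded]
    wrong = [t for t in responded if t.response != t.correct_side]
    late = [t for t in responded if t.response == t.correct_side and t.late_flag]
    correct = [
        t for t in responded if t.response == t.correct_side and not t.late_flag
    ]
    return go, omitted, responded, wrong, late, correct


def compute_behavioral_summary(
    trials: Sequence[TrialRecord],
    ssrt_method: Literal["integration", "mean"] = "integration",
) -> BehavioralSummary:
    """Summarise one subject's trial list into Table-1-style metrics.

    Raises
    ------
    DegenerateInputError
        Fewer than 2 responded Go trials (ICV undefined).
    ValueError
        Mean correct Go RT is zero (cannot form a ratio).
    """
    trials = list(trials)
    go, omitted, responded, wrong, late, correct = _go_partition(trials)
    stop = [t for t in trials if t.trial_type == "stop"]
    if len(responded) < 2:
        raise DegenerateInputError(
            f"need at least 2 responded Go trials, got {len(responded)}"
        )
    rts = np.array([t.rt for t in correct], dtype=float)
    if rts.size < 2:
        raise DegenerateInputError(
            "need at least 2 correct on-time Go responses for ICV"
        )
    mean_go = float(np.mean(rts))
    if mean_go == 0.0:
        raise ValueError("mean Go RT is zero; ICV undefined")
    sd_go = float(np.std(rts, ddof=1))

    n_go, n_stop = len(go), len(stop)
    responded_stops = [t for t in stop if t.responded]
    stop_rts = [t.rt for t in responded_stops if t.rt is not None]
    p_commission = 100.0 * len(responded_stops) / n_stop if n_stop else float("nan")
    summary = BehavioralSummary(
        icv=sd_go / mean_go,
        mean_go_rt=mean_go,
        sd_go_rt=sd_go,
        stop_rt=float(np.mean(stop_rts)) if stop_rts else float("nan"),
        mean_ssd=float(np.mean([t.ssd for t in stop])) if stop else float("nan"),
        ssrt=float("nan"),
        p_omission=100.0 * len(omitted) / n_go if n_go else float("nan"),
        p_choice_error=100.0 * len(wrong) / n_go if n_go else float("nan"),
        p_commission=p_commission,
        n_go=n_go,
        n_stop=n_stop,
        go_error_rate=(len(wrong) + len(omitted) + len(late)) / n_go
        if n_go
        else float("nan"),
    )
    if stop:
        summary.ssrt, summary.ssrt_reliable = _ssrt(
            rts, summary.mean_ssd, p_commission / 100.0, ssrt_method
        )
    return summary


def _ssrt(go_rts: np.ndarray, mean_ssd: float, p_respond: float, method: str):
    reliable = True
    if method == "mean":
        return float(np.mean(go_rts)) - mean_ssd, reliable
    if method != "integration":
        raise ValueError(f"unknown SSRT method {method!r}")
    if p_respond <= 0.0 or p_respond >= 1.0:
        warnings.warn(
            "p(respond|stop) at the boundary; integration SSRT uses a "
            "boundary quantile and is unreliable",
            stacklevel=3,
        )
        reliable = False
        p_respond = min(max(p_respond, 0.0), 1.0)
    quant = float(np.quantile(go_rts, p_respond, method="higher"))
    return quant - mean_ssd, reliable


def compute_ssrt(
    trials: Sequence[TrialRecord],
    method: Literal["integration", "mean"] = "integration",
) -> float:
    """Stop-signal RT from the race model.

    The integration method takes the p(respond|stop)-quantile of the Go RT
    distribution minus the mean SSD; the mean method uses mean Go RT minus
    mean SSD. The staircase targets p(respond|stop) = 0.5, where the two
    coincide for symmetric RT distributions.
    """
    stop = [t for t in trials if t.trial_type == "stop"]
    if not stop:
        raise DegenerateInputError("SSRT requires at least one stop trial")
    summary = compute_behavioral_summary(trials, ssrt_method=method)
    return summary.ssrt


def apply_exclusion(summary: BehavioralSummary, mean_fd: float) -> ExclusionDecision:
    """Inclusion gate: >20% Go errors or mean FD > 0.5 mm excludes.

    Both inequalities are strict; a subject exactly at a limit is retained.
    """
    if mean_fd < 0:
        raise ValueError("mean_fd must be nonnegative")
    reasons = []
    if summary.go_error_rate > GO_ERROR_LIMIT:
        reasons.append("go_errors")
    if mean_fd > MEAN_FD_LIMIT:
        reasons.append("motion")
    return ExclusionDecision(include=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# IO


def read_trials_tsv(path) -> list[TrialRecord]:
    """Read a trial-level TSV (missing values as empty fields)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        rt = getattr(row, "rt", None)
        ssd = getattr(row, "ssd", None)
        response = getattr(row, "response", "none")
        if isinstance(response, float) and np.isnan(response):
            response = "none"
        records.append(
            TrialRecord(
                trial_index=int(row.trial_index),
                trial_type=str(row.trial_type),
                onset=float(row.onset),
                correct_side=str(row.correct_side),
                response=str(response),
                rt=None if rt is None or pd.isna(rt) else float(rt),
                ssd=None if ssd is None or pd.isna(ssd) else float(ssd),
                late_flag=bool(getattr(row, "late_flag", False)),
            )
        )
    return records


def write_trials_tsv(trials: Iterable[TrialRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "trial_index": t.trial_index,
                "trial_type": t.trial_type,
                "onset": t.onset,
                "ssd": t.ssd,
                "response": t.response,
                "correct_side": t.correct_side,
                "rt": t.rt,
                "late_flag": t.late_flag,
            }
            for t in trials
        ]
    ).to_csv(path, sep="\t", index=False)


def summaries_to_frame(summaries: dict[str, BehavioralSummary]) -> pd.DataFrame:
    """Stack per-subject summaries into a cohort table (subjects as rows)."""
    return pd.DataFrame({sid: s.to_series() for sid, s in summaries.items()}).T
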
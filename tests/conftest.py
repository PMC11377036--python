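import numpy as np
import pandas as pd
import pytest

from attnconn import simulate
from attnconn.sst import TrialRecord


@pytest.fixture(scope="session")
def sst_trials():
    """One deterministic full-length simulated SST run."""
    return simulate.simulate_sst_trials(rng=42)


@pytest.fixture(scope="session")
def dense_events():
    """Realistic dense SST event table covering a 300-volume run at TR 2.2."""
    trials = simulate.simulate_sst_trials(rng=0, n_go=280, n_stop=50)
    ev = simulate.trials_to_events(trials)
    return ev[ev["onset"] < 300 * 2.2 - 20].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic three-wave connectome cohort (default config)."""
    return simulate.simulate_connectome_cohort(seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Very small cohort for leakage / determinism checks."""
    return simulate.simulate_connectome_cohort(
        n_subjects=60, n_rois=16, n_positive_edges=5, n_negative_edges=5,
        seed=5,
    )


def make_go_trials(rts, correct=True, late=None, side="left"):
    """Hand-build a list of Go trials from RTs (None = omission)."""
    late = late or [False] * len(rts)
    out = []
    for i, rt in enumerate(rts):
        if rt is None:
            out.append(TrialRecord(i, "go", i * 2.0, side))
        else:
            resp = side if correct else ("right" if side == "left" else "left")
            out.append(
                TrialRecord(i, "go", i * 2.0, side, response=resp,
                            rt=float(rt), late_flag=late[i])
            )
    return out


def make_stop_trials(n, responded, ssd=300.0, rt=450.0, start_index=1000):
    out = []
    for i in range(n):
        resp = responded[i] if isinstance(responded, (list, tuple)) else responded
        out.append(
            TrialRecord(
                start_index + i, "stop", (start_index + i) * 2.0, "left",
                response="left" if resp else "none",
                rt=rt if resp else None, ssd=ssd,
            )
        )
    return out
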
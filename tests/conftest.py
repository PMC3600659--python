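import logging

import numpy as np
import pandas as pd
import pytest

from revlearn import cohort, eegsim, erp, task

logging.getLogger("revlearn").setLevel(logging.ERROR)


@pytest.fixture
def default_config():
    return task.TaskConfig()


@pytest.fixture
def schedule(default_config):
    return task.build_schedule(default_config, seed=123)


@pytest.fixture
def quiet_eeg_config():
    """Zero-noise EEG config for exact round-trip checks."""
    return eegsim.SynthEEGConfig(noise_sd=0.0)


@pytest.fixture
def flat_epochs():
    """Deterministic all-zero epochs: 6 PF + 4 NF, 3 channels."""
    cfg = eegsim.SynthEEGConfig()
    data = np.zeros((10, 3, cfg.n_samples))
    return erp.EpochSet(data=data, times=cfg.times,
                        channels=list(cfg.channels),
                        conditions=np.array(["PF"] * 6 + ["NF"] * 4),
                        sfreq=cfg.sfreq)


def always_choose(schedule, option):
    """Play a full schedule with a constant chooser; returns the log of
    (feedback, accurate) pairs — the brute-force task oracle used by
    contingency tests."""
    state = task.TrialState()
    out = []
    for i in range(schedule.n_trials):
        fb, state = task.play_trial(schedule, state, option)
        out.append((fb, option == schedule.correct[i]))
    return out, state


@pytest.fixture
def tiny_cohort_config():
    return cohort.CohortConfig(group_sizes={"HC": 4, "PG": 4, "CDI": 4})


def make_trial_log(accurate_seq, latency=500.0, n_phases=4, per_phase=40):
    """Construct a synthetic single-participant trial log from a
    accuracy sequence (cycled to full length)."""
    n = n_phases * per_phase
    acc = [bool(accurate_seq[i % len(accurate_seq)]) for i in range(n)]
    rows = []
    for i in range(n):
        rows.append({
            "participant_id": "X01",
            "phase": i // per_phase + 1,
            "trial": i % per_phase + 1,
            "block": (i % per_phase) // 10 + 1,
            "accurate": acc[i],
            "latency_ms": latency,
        })
    return pd.DataFrame(rows)
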
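import numpy as np
import pandas as pd
import pytest

from satmodels.data_model import TrialTable


def make_trials(subject="s00", session="placebo", cue="accuracy", block=1,
                n=10, rt_ms=None, correct=None, responded=None, seed=0):
    """Hand-built valid trial rows for data-model tests."""
    rng = np.random.default_rng(seed)
    rt_ms = np.asarray(rt_ms if rt_ms is not None
                       else rng.uniform(300, 900, n))
    correct = np.asarray(correct if correct is not None
                         else rng.random(n) < 0.85)
    responded = np.asarray(responded if responded is not None
                           else np.ones(n, dtype=bool))
    direction = np.where(rng.random(n) < 0.5, "left", "right").astype(object)
    opposite = np.where(direction == "left", "right", "left")
    response = np.where(responded,
                        np.where(correct, direction, opposite),
                        "none").astype(object)
    return pd.DataFrame({
        "subject": subject, "session": session, "block": block, "cue": cue,
        "direction": direction, "response": response,
        "correct": np.where(responded, correct, False),
        "rt_ms": np.where(responded, rt_ms, np.nan),
        "responded": responded,
    })


def make_table(n_per_cell=20, subjects=("s00", "s01"), seed=0) -> TrialTable:
    """Complete 2-session x 2-cue table for several subjects."""
    frames = []
    k = 0
    for subject in subjects:
        for session in ("drug", "placebo"):
            for cue in ("speed", "accuracy"):
                frames.append(make_trials(subject, session, cue,
                                          n=n_per_cell, seed=seed + k))
                k += 1
    return TrialTable(pd.concat(frames, ignore_index=True))


@pytest.fixture
def small_table():
    return make_table()
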
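"""Shared fixtures: small deterministic recordings built by the simulator."""

import numpy as np
import pandas as pd
import pytest

from mipipe import EpochedRecording, SimulationConfig, generate_recording
from mipipe.recording import select_trials


@pytest.fixture(scope="session")
def small_recording():
    """One 120-trial session with planted ERD, moderate size for speed."""
    cfg = SimulationConfig(seed=42, n_sessions=1, trials_per_session=120,
                           erd_depth=(0.5,))
    rec, truth = generate_recording(cfg)
    return rec, truth


@pytest.fixture(scope="session")
def nonhold_small(small_recording):
    rec, _ = small_recording
    return select_trials(rec, tasks=("left", "right"))


@pytest.fixture()
def toy_recording():
    """Handmade 4-trial recording with deterministic content."""
    rng = np.random.default_rng(0)
    fs = 200.0
    times = np.arange(-200, 201) / fs
    data = rng.standard_normal((4, 19, times.size))
    meta = pd.DataFrame({
        "trial": [0, 1, 2, 3],
        "task": ["left", "right", "hold", "left"],
        "session": [1, 1, 1, 1],
        "day": [1, 1, 1, 1],
    })
    return EpochedRecording(data=data, sampling_rate=fs, times=times, meta=meta)
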
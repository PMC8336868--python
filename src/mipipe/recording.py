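"""Epoched EEG container and trial selection.

An :class:`EpochedRecording` holds a trials x channels x samples array in
microvolts, cut around the action onset of each motor-imagery trial
(window [-1, +1] s by default: the final resting second, then the 1-s
action).  Per-trial metadata (task label, session, day, chronological
trial index) travels alongside as a DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyRecordingError
from .montage import Montage, standard_montage

TASKS = ("left", "right", "hold")

META_COLUMNS = ("trial", "task", "session", "day")


@dataclass
class EpochedRecording:
    """trials x channels x samples epochs with per-trial metadata.

    ``times`` is seconds relative to action onset, strictly increasing
    with uniform step 1/sampling_rate.  Channel order follows the montage.
    """

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    meta: pd.DataFrame
    montage: Montage = field(default_factory=standard_montage)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.data.ndim != 3:
            raise ConfigurationError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if n_channels != len(self.montage.channels):
            raise ConfigurationError(
                f"data has {n_channels} channels, montage has "
                f"{len(self.montage.channels)}"
            )
        if self.times.shape != (n_samples,):
            raise ConfigurationError("times length must match data samples")
        step = 1.0 / self.sampling_rate
        if n_samples > 1 and not np.allclose(
            np.diff(self.times), step, rtol=0, atol=step * 1e-6
        ):
            raise ConfigurationError("times must increase uniformly by 1/fs")
        if not np.isfinite(self.data).all():
            raise ConfigurationError("data contains non-finite values")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ConfigurationError(f"meta is missing columns {missing}")
        if len(self.meta) != n_trials:
            raise ConfigurationError("meta length must match number of trials")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic shape accessors -------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def channels(self) -> tuple[str, ...]:
        return self.montage.channels

    # -- analysis windows ------------------------------------------------
    def window_mask(self, role: str) -> np.ndarray:
        """Boolean sample mask for the 'task' [0, 1) s or 'rest' [-1, 0) s window."""
        if role == "task":
            return (self.times >= 0.0) & (self.times < 1.0)
        if role == "rest":
            return (self.times >= -1.0) & (self.times < 0.0)
        raise ConfigurationError(f"unknown window role {role!r}")

    def channel_index(self, label: str) -> int:
        return self.montage.index(label)

    def select(self, tasks=None, sessions=None, days=None) -> "EpochedRecording":
        return select_trials(self, tasks=tasks, sessions=sessions, days=days)

    def copy_with(self, **kwargs) -> "EpochedRecording":
        out = replace(self, **kwargs)
        return out


def select_trials(
    rec: EpochedRecording, tasks=None, sessions=None, days=None
) -> EpochedRecording:
    """Subset trials by task label / session / day, preserving order.

    Raises :class:`EmptyRecordingError` when nothing survives.
    """
    mask = np.ones(rec.n_trials, dtype=bool)
    if tasks is not None:
        mask &= rec.meta["task"].isin(set(tasks)).to_numpy()
    if sessions is not None:
        mask &= rec.meta["session"].isin(set(sessions)).to_numpy()
    if days is not None:
        mask &= rec.meta["day"].isin(set(days)).to_numpy()
    if not mask.any():
        raise EmptyRecordingError(
            f"selection tasks={tasks} sessions={sessions} days={days} "
            "matched no trials"
        )
    return EpochedRecording(
        data=rec.data[mask],
        sampling_rate=rec.sampling_rate,
        times=rec.times,
        meta=rec.meta.loc[mask],
        montage=rec.montage,
    )


def concat_recordings(recs: list[EpochedRecording]) -> EpochedRecording:
    """Concatenate recordings (e.g. per-session or per-day files) along trials."""
    if not recs:
        raise EmptyRecordingError("no recordings to concatenate")
    first = recs[0]
    for r in recs[1:]:
        if r.sampling_rate != first.sampling_rate or r.n_samples != first.n_samples:
            raise ConfigurationError("recordings differ in rate or epoch length")
    return EpochedRecording(
        data=np.concatenate([r.data for r in recs], axis=0),
        sampling_rate=first.sampling_rate,
        times=first.times,
        meta=pd.concat([r.meta for r in recs], ignore_index=True),
        montage=first.montage,
    )
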
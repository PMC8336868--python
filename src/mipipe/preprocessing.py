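"""Band-pass filtering, the frequency-band scan grid, and trial-block ERPs.

The analysis unit downstream of this module is the *trial-block*: the
arithmetic mean of 20 consecutive same-task trials within one session,
which averages out background EEG and leaves a pronounced event-related
potential.  Filtering is zero-phase (forward-backward Butterworth) so the
ERP deflection latencies the pipeline reads at 0.35/0.55/0.65 s are not
shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .recording import EpochedRecording


@dataclass(frozen=True)
class BandDefinition:
    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ConfigurationError(f"invalid band {self.lo}-{self.hi} Hz")

    def label(self) -> str:
        return self.name or f"{self.lo:g}-{self.hi:g}Hz"


#: the five screening bands used for the node-degree frequency scan
FIVE_BAND_GRID: tuple[BandDefinition, ...] = (
    BandDefinition(0.53, 4.0, "0.53-4Hz"),
    BandDefinition(3.0, 6.0, "3-6Hz"),
    BandDefinition(5.0, 10.0, "5-10Hz"),
    BandDefinition(8.0, 16.0, "8-16Hz"),
    BandDefinition(15.0, 30.0, "15-30Hz"),
)

#: the band used for ERP-network construction
ANALYSIS_BAND = BandDefinition(3.0, 30.0, "3-30Hz")


def bandpass(rec: EpochedRecording, band: BandDefinition, order: int = 4,
             pad_seconds: float = 0.5) -> EpochedRecording:
    """Zero-phase Butterworth band-pass applied per trial, per channel.

    Uses forward-backward second-order sections with reflection padding
    (``pad_seconds`` worth of samples, capped by epoch length), so the
    pass-band gain is the squared magnitude response and phase is zero.
    """
    nyquist = rec.sampling_rate / 2.0
    if band.hi >= nyquist:
        raise ConfigurationError(
            f"band edge {band.hi} Hz violates Nyquist ({nyquist} Hz)"
        )
    sos = sps.butter(order, (band.lo, band.hi), btype="bandpass",
                     fs=rec.sampling_rate, output="sos")
    padlen = min(int(round(pad_seconds * rec.sampling_rate)),
                 rec.n_samples - 2)
    filtered = sps.sosfiltfilt(sos, rec.data, axis=-1, padtype="odd",
                               padlen=padlen)
    return EpochedRecording(
        data=filtered, sampling_rate=rec.sampling_rate, times=rec.times,
        meta=rec.meta, montage=rec.montage,
    )


@dataclass
class TrialBlockERP:
    """Mean of ``n_trials`` consecutive same-task trials (channels x samples)."""

    data: np.ndarray
    block_index: int          # 1-based within (day, session, task) group
    session: int
    day: int
    task_label: str
    n_trials: int
    sampling_rate: float
    times: np.ndarray
    channels: tuple[str, ...]
    start_trial: int          # chronological index of the first member trial

    def window_slice(self, role: str) -> np.ndarray:
        if role == "task":
            mask = (self.times >= 0.0) & (self.times < 1.0)
        elif role == "rest":
            mask = (self.times >= -1.0) & (self.times < 0.0)
        else:
            raise ConfigurationError(f"unknown window role {role!r}")
        return self.data[:, mask]


def make_trial_blocks(rec: EpochedRecording, block_size: int = 20
                      ) -> list[TrialBlockERP]:
    """Chunk trials into per-(day, session, task) blocks and average.

    Trials keep chronological order inside each group; the trailing
    incomplete chunk is dropped so every block averages exactly
    ``block_size`` trials.  Blocks never span sessions or task labels.
    """
    if block_size < 2:
        raise ConfigurationError("block_size must be at least 2")
    blocks: list[TrialBlockERP] = []
    meta = rec.meta
    for (day, session, task), grp in meta.groupby(["day", "session", "task"],
                                                  sort=True):
        order = grp.sort_values("trial").index.to_numpy()
        n_full = len(order) // block_size
        for b in range(n_full):
            members = order[b * block_size : (b + 1) * block_size]
            blocks.append(
                TrialBlockERP(
                    data=rec.data[members].mean(axis=0),
                    block_index=b + 1,
                    session=int(session),
                    day=int(day),
                    task_label=str(task),
                    n_trials=block_size,
                    sampling_rate=rec.sampling_rate,
                    times=rec.times,
                    channels=rec.channels,
                    start_trial=int(meta.loc[members[0], "trial"]),
                )
            )
    blocks.sort(key=lambda blk: blk.start_trial)
    return blocks


def day_synchronize(series_by_day: dict[int, np.ndarray]) -> np.ndarray:
    """Average per-day block series element-wise at matching block index.

    Days are trimmed to the shortest day's length first, mirroring the
    'synchronize and average across days' treatment of block series.
    """
    if not series_by_day:
        raise ConfigurationError("no day series supplied")
    arrays = [np.asarray(v, dtype=float) for v in series_by_day.values()]
    n = min(len(a) for a in arrays)
    if n == 0:
        raise ConfigurationError("a day series is empty")
    return np.mean([a[:n] for a in arrays], axis=0)
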
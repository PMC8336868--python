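"""Readers and writers: plain epochs table, events CSV, and EDF.

Formats
-------
* **Epochs table** — a text format for epoched data: ``#``-prefixed
  metadata header (``sampling_rate``, ``onset_index``, ``channels``, one
  ``trial_meta`` line per trial with task/session/day), then CSV rows
  ``trial,channel,sample_index,value`` at full float precision.  The
  write/read round trip is exact.
* **Events CSV** — sidecar for continuous records with columns
  ``trial_index,session,day,task_label,onset_sample``.
* **EDF** — continuous multichannel records.  Reading goes through
  ``mne.io.read_raw_edf``; writing uses a minimal built-in EDF writer
  (16-bit samples, one data record per second) sufficient for the
  19-channel montage produced by the simulator.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .montage import CHANNELS_1020, Montage, normalize_label, standard_montage
from .recording import EpochedRecording

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("trial_index", "session", "day", "task_label", "onset_sample")


# ---------------------------------------------------------------------------
# epochs table
# ---------------------------------------------------------------------------

def write_epochs_table(rec: EpochedRecording, path) -> None:
    """Serialize an epoched recording losslessly to the plain-text table."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate={rec.sampling_rate!r}\n")
        onset_index = int(np.argmin(np.abs(rec.times)))
        fh.write(f"# onset_index={onset_index}\n")
        fh.write(f"# n_samples={rec.n_samples}\n")
        fh.write(f"# channels={','.join(rec.channels)}\n")
        for _, row in rec.meta.iterrows():
            fh.write(
                f"# trial_meta={int(row['trial'])},{row['task']},"
                f"{int(row['session'])},{int(row['day'])}\n"
            )
        fh.write("trial,channel,sample_index,value\n")
        for t in range(rec.n_trials):
            for c, ch in enumerate(rec.channels):
                values = rec.data[t, c]
                lines = "\n".join(
                    f"{t},{ch},{s},{float(v)!r}" for s, v in enumerate(values)
                )
                fh.write(lines + "\n")


def read_epochs_table(path) -> EpochedRecording:
    """Parse the epochs table back into an :class:`EpochedRecording`."""
    path = Path(path)
    header: dict[str, str] = {}
    trial_meta = []
    body_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].strip().partition("=")
        key = key.strip()
        if key == "trial_meta":
            trial_meta.append(value.strip())
        else:
            header[key] = value.strip()
    for required in ("sampling_rate", "onset_index", "channels"):
        if required not in header:
            raise FormatError(f"epochs table missing {required} header")
    fs = float(header["sampling_rate"])
    onset_index = int(header["onset_index"])
    channels = tuple(header["channels"].split(","))

    body = pd.read_csv(path, skiprows=body_start, float_precision="round_trip")
    expected_cols = {"trial", "channel", "sample_index", "value"}
    if set(body.columns) != expected_cols:
        raise FormatError(f"epochs table columns must be {sorted(expected_cols)}")

    trials = sorted(body["trial"].unique())
    counts = body.groupby("trial").size()
    if counts.nunique() != 1:
        raise FormatError("ragged trials: unequal sample counts per trial")
    n_samples = int(counts.iloc[0]) // len(channels)
    if n_samples * len(channels) != counts.iloc[0]:
        raise FormatError("sample count not divisible by channel count")

    data = np.empty((len(trials), len(channels), n_samples))
    ch_index = {c: i for i, c in enumerate(channels)}
    for (t, ch), grp in body.groupby(["trial", "channel"], sort=False):
        grp = grp.sort_values("sample_index")
        if len(grp) != n_samples:
            raise FormatError(f"trial {t} channel {ch}: ragged sample count")
        data[trials.index(t), ch_index[ch]] = grp["value"].to_numpy()

    rows = []
    for entry in trial_meta:
        t, task, session, day = entry.split(",")
        rows.append({"trial": int(t), "task": task, "session": int(session),
                     "day": int(day)})
    if len(rows) != len(trials):
        raise FormatError("trial_meta entries do not match trial count")
    if channels != CHANNELS_1020:
        raise FormatError("epochs table channels must follow the canonical montage")
    times = (np.arange(n_samples) - onset_index) / fs
    return EpochedRecording(
        data=data, sampling_rate=fs, times=times, meta=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# events CSV
# ---------------------------------------------------------------------------

def write_events_csv(events: pd.DataFrame, path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"events table missing columns {missing}")
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"events table missing columns {missing}")
    per_session = events.groupby(["day", "session"])["onset_sample"]
    if not (per_session.apply(lambda s: s.is_monotonic_increasing)).all():
        raise FormatError("onset samples must increase within a session record")
    return events


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIGITAL_MIN = -32768
_EDF_DIGITAL_MAX = 32767


def _pad_field(value, width) -> bytes:
    text = str(value)
    if len(text) > width:
        raise FormatError(f"EDF header field too long: {text!r}")
    return text.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, sampling_rate: float,
              channels=CHANNELS_1020) -> None:
    """Write a continuous channels x samples signal (µV) as 16-bit EDF.

    One data record per second; the tail is zero-padded to a whole
    record.  Physical range is symmetric around zero, chosen per channel
    from the data, so quantization error is at most one step of
    ``(2 * max|x|) / 65535``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(channels):
        raise ConfigurationError("data must be channels x samples")
    fs = int(round(sampling_rate))
    if fs <= 0 or abs(fs - sampling_rate) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    n_ch, n = data.shape
    n_records = math.ceil(n / fs)
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n] = data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0) * 1.0001
    # EDF physical min/max are 8-char ASCII fields
    phys_max = np.array([float(f"{p:.6g}") + 1e-6 for p in phys_max])
    phys_min = -phys_max

    header = b""
    header += _pad_field("0", 8)                      # version
    header += _pad_field("X", 80)                     # patient id
    header += _pad_field("X", 80)                     # recording id
    header += _pad_field("01.01.00", 8)               # start date
    header += _pad_field("00.00.00", 8)               # start time
    header += _pad_field(256 * (n_ch + 1), 8)         # header bytes
    header += _pad_field("", 44)                      # reserved
    header += _pad_field(n_records, 8)
    header += _pad_field(1, 8)                        # record duration (s)
    header += _pad_field(n_ch, 4)

    header += b"".join(_pad_field(ch, 16) for ch in channels)
    header += b"".join(_pad_field("", 80) for _ in channels)   # transducer
    header += b"".join(_pad_field("uV", 8) for _ in channels)  # dimension
    header += b"".join(_pad_field(f"{p:.6g}", 8) for p in phys_min)
    header += b"".join(_pad_field(f"{p:.6g}", 8) for p in phys_max)
    header += b"".join(_pad_field(_EDF_DIGITAL_MIN, 8) for _ in channels)
    header += b"".join(_pad_field(_EDF_DIGITAL_MAX, 8) for _ in channels)
    header += b"".join(_pad_field("", 80) for _ in channels)   # prefiltering
    header += b"".join(_pad_field(fs, 8) for _ in channels)
    header += b"".join(_pad_field("", 32) for _ in channels)   # reserved

    scale = (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN) / (phys_max - phys_min)
    with Path(path).open("wb") as fh:
        fh.write(header)
        for r in range(n_records):
            chunk = padded[:, r * fs : (r + 1) * fs]
            digital = np.round(
                (chunk - phys_min[:, None]) * scale[:, None] + _EDF_DIGITAL_MIN
            ).astype("<i2")
            fh.write(digital.tobytes())


def read_edf(path, events: pd.DataFrame,
             epoch_window: tuple[float, float] = (-1.0, 1.0),
             montage: Montage | None = None) -> EpochedRecording:
    """Load one continuous EDF record and cut epochs at the given events.

    ``events`` follows the events-CSV schema; its ``onset_sample`` values
    index the continuous record in this file.  Channels are matched
    case-insensitively against the montage (reference suffixes stripped,
    T7/T8/P7/P8 normalized) and reordered canonically.  Trials whose
    window does not fit inside the record are dropped with a warning.
    """
    import mne

    montage = montage or standard_montage()
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - backend message varies
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc

    label_map = {}
    for name in raw.ch_names:
        try:
            label_map.setdefault(normalize_label(name), name)
        except ConfigurationError:
            continue
    missing = [c for c in montage.channels if c not in label_map]
    if missing:
        raise FormatError(
            f"EDF file {path} lacks montage channels: {', '.join(missing)}"
        )
    picks = [raw.ch_names.index(label_map[c]) for c in montage.channels]
    signal = raw.get_data()[picks] * 1e6  # mne returns volts
    fs = float(raw.info["sfreq"])

    lo = int(round(epoch_window[0] * fs))
    hi = int(round(epoch_window[1] * fs))
    times = np.arange(lo, hi + 1) / fs
    n = signal.shape[1]

    epochs, rows, dropped = [], [], 0
    for _, ev in events.iterrows():
        onset = int(ev["onset_sample"])
        start, stop = onset + lo, onset + hi + 1
        if start < 0 or stop > n:
            dropped += 1
            continue
        epochs.append(signal[:, start:stop])
        rows.append(
            {"trial": int(ev["trial_index"]), "task": str(ev["task_label"]),
             "session": int(ev["session"]), "day": int(ev["day"])}
        )
    if dropped:
        logger.warning("dropped %d trial(s) outside the EDF record bounds", dropped)
    if not epochs:
        raise FormatError(f"no epochs could be cut from {path}")
    return EpochedRecording(
        data=np.stack(epochs), sampling_rate=fs, times=times,
        meta=pd.DataFrame(rows), montage=montage,
    )


def session_events(records, day: int = 1) -> list[pd.DataFrame]:
    """Events tables for :func:`mipipe.synthetic.simulate_sessions` output."""
    tables = []
    trial = 0
    for s, rec in enumerate(records):
        rows = []
        for onset, label in zip(rec.onset_samples, rec.labels):
            rows.append(
                {"trial_index": trial, "session": s + 1, "day": day,
                 "task_label": label, "onset_sample": onset}
            )
            trial += 1
        tables.append(pd.DataFrame(rows))
    return tables
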
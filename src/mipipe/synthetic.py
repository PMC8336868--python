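"""Synthetic motor-imagery EEG sessions with known ground truth.

The generator emulates the cued left/right/hold grasp-imagery paradigm the
analysis targets: sessions of short trials (random 1.5-2.5 s pause, 1 s
action), a 19-channel 10-20 montage, contralateral Mu-band ERD during the
action window, a stereotyped ERP with deflections near 0.35 / 0.55 /
0.65 s (negative, positive, negative), spatially correlated 1/f
background, and session-indexed trend profiles (ERD depth, shared ERP
gain) that mimic feedback vs non-feedback training courses.

Signal model per channel, per session record (all in microvolts):

    x(t) = pink(t) + M s(t) + mu(t) * env(t) + g_s w_c ERP(t - onset)

* ``pink``  - channel-private 1/f^a noise (a = ``noise_exponent``).
* ``M s``   - K shared broadband sources through a fixed random mixing
  matrix; this plants non-trivial baseline inter-channel correlation.
* ``mu``    - narrowband oscillation inside ``mu_band`` at the
  sensorimotor channels (C3, C4, half-amplitude Cz); during the 1-s
  action of a left (right) MI trial its envelope at C4 (C3) is scaled by
  ``1 - erd_depth[session]``.
* ``ERP``   - three Gaussian-windowed deflections (sigma 40 ms) at
  0.35/0.55/0.65 s, added on non-hold action windows with spatial weight
  ``w_c`` (strongest centrally) times the per-session ``shared_gain``
  plus small per-channel gain jitter.

All randomness flows from one ``numpy`` Generator seeded by
``SimulationConfig.seed``: the same config is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import fft as spfft
from scipy import signal as sps

from .errors import ConfigurationError
from .montage import POSITIONS_2D, Montage, standard_montage
from .recording import EpochedRecording

_TASK_ORDER = ("left", "right", "hold")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the simulated paradigm.

    Defaults follow the emulated protocol: 3 sessions of 300 trials,
    1.5-2.5 s random pause + 1 s action, equal left/right/hold mix,
    9-12 Hz Mu rhythm.  Amplitudes are in microvolts.
    """

    sampling_rate: float = 200.0
    n_sessions: int = 3
    trials_per_session: int = 300
    pause_range: tuple[float, float] = (1.5, 2.5)
    action_duration: float = 1.0
    task_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    mu_band: tuple[float, float] = (9.0, 12.0)
    erd_depth: tuple[float, ...] = (0.4, 0.4, 0.4)
    erp_amplitudes: tuple[float, float, float] = (-8.0, 12.0, -8.0)
    shared_gain: tuple[float, ...] = (1.0, 1.0, 1.0)
    noise_exponent: float = 1.0
    seed: int = 0
    # second-order knobs (fixed study conditions, rarely touched)
    day: int = 1
    mu_rms: float = 6.0            # Mu-rhythm amplitude at C3/C4
    background_rms: float = 9.0    # private 1/f noise per channel
    shared_noise_rms: float = 6.0  # broadband common-source noise per channel
    n_shared_sources: int = 4
    erp_latencies: tuple[float, float, float] = (0.35, 0.55, 0.65)
    erp_sigma: float = 0.040       # Gaussian deflection width, seconds
    erp_gain_jitter: float = 0.1   # relative per-channel/trial gain sd

    def __post_init__(self) -> None:
        # scalar or uniform profiles broadcast to n_sessions
        for name in ("erd_depth", "shared_gain"):
            value = getattr(self, name)
            profile = (value,) if np.isscalar(value) else tuple(value)
            if len(profile) != self.n_sessions and len(set(profile)) == 1:
                profile = (profile[0],) * self.n_sessions
            object.__setattr__(self, name, profile)

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ConfigurationError("need at least one session and one trial")
        if abs(sum(self.task_mix) - 1.0) > 1e-9:
            raise ConfigurationError("task_mix must sum to 1")
        if any(m < 0 for m in self.task_mix):
            raise ConfigurationError("task_mix proportions must be >= 0")
        if self.pause_range[0] > self.pause_range[1] or self.pause_range[0] < 1.0:
            raise ConfigurationError("pause_range must be increasing and >= 1 s")
        if self.action_duration <= 0:
            raise ConfigurationError("action_duration must be positive")
        if len(self.erd_depth) != self.n_sessions:
            raise ConfigurationError("erd_depth needs one value per session")
        if len(self.shared_gain) != self.n_sessions:
            raise ConfigurationError("shared_gain needs one value per session")
        if any(not (0.0 <= d < 1.0) for d in self.erd_depth):
            raise ConfigurationError("erd_depth values must lie in [0, 1)")
        if not (0 < self.mu_band[0] < self.mu_band[1] < self.sampling_rate / 2):
            raise ConfigurationError("mu_band must fit below Nyquist")

    def with_profiles(self, erd_depth, shared_gain, seed=None) -> "SimulationConfig":
        return replace(
            self,
            erd_depth=tuple(erd_depth),
            shared_gain=tuple(shared_gain),
            seed=self.seed if seed is None else seed,
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    erd_depth: tuple[float, ...]
    shared_gain: tuple[float, ...]
    mu_band: tuple[float, float]
    labels: tuple[tuple[str, ...], ...]      # per session
    onset_samples: tuple[tuple[int, ...], ...]  # per session, continuous record

    def __post_init__(self) -> None:
        n = len(self.erd_depth)
        if not (len(self.shared_gain) == len(self.labels) == len(self.onset_samples) == n):
            raise ConfigurationError("ground-truth vectors must share n_sessions")


class SessionRecord(NamedTuple):
    """One continuous session: channels x samples signal plus its events."""

    signal: np.ndarray
    onset_samples: tuple[int, ...]
    labels: tuple[str, ...]


def _task_sequence(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Balanced label sequence by largest-remainder rounding, then shuffled."""
    n = cfg.trials_per_session
    raw = [m * n for m in cfg.task_mix]
    counts = [math.floor(r) for r in raw]
    remainders = np.array(raw) - np.array(counts)
    for i in np.argsort(-remainders)[: n - sum(counts)]:
        counts[int(i)] += 1
    labels = [t for t, c in zip(_TASK_ORDER, counts) for _ in range(c)]
    return [labels[i] for i in rng.permutation(n)]


def _pink_noise(rng, shape, n, fs, exponent, rms):
    """1/f^a noise via spectral shaping, flat below 0.5 Hz, unit-free rms.

    Shaping runs on the next fast FFT length and is cropped back, which
    keeps long sessions cheap regardless of their prime factorization.
    """
    nf = spfft.next_fast_len(n)
    white = rng.standard_normal(shape + (n,))
    spec = spfft.rfft(white, n=nf, axis=-1)
    f = spfft.rfftfreq(nf, 1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0.5
    scale[nz] = (0.5 / f[nz]) ** (exponent / 2.0)
    x = spfft.irfft(spec * scale, n=nf, axis=-1)[..., :n]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def _erp_template(cfg: SimulationConfig) -> np.ndarray:
    """Deflection template over the 1-s action window."""
    na = int(round(cfg.action_duration * cfg.sampling_rate))
    t = np.arange(na) / cfg.sampling_rate
    template = np.zeros(na)
    for amp, lat in zip(cfg.erp_amplitudes, cfg.erp_latencies):
        template += amp * np.exp(-((t - lat) ** 2) / (2 * cfg.erp_sigma**2))
    return template


def _spatial_weights(montage: Montage) -> np.ndarray:
    """ERP scalp weighting: strongest centrally, decaying with grid distance."""
    w = np.empty(len(montage.channels))
    for i, ch in enumerate(montage.channels):
        x, y = POSITIONS_2D[ch]
        d2 = x * x + y * y
        w[i] = 0.3 + 0.7 * math.exp(-d2 / 0.36)
    return w


def _simulate_session(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    session_index: int,
    montage: Montage,
    mixing: np.ndarray,
    sos_mu,
) -> SessionRecord:
    fs = cfg.sampling_rate
    na = int(round(cfg.action_duration * fs))
    lead = int(round(fs))  # head/tail padding so every epoch window fits

    labels = _task_sequence(cfg, rng)
    pauses = rng.uniform(*cfg.pause_range, size=cfg.trials_per_session)
    pause_samps = np.round(pauses * fs).astype(int)

    onsets = []
    pos = lead
    for p in pause_samps:
        pos += int(p)
        onsets.append(pos)
        pos += na
    n = pos + lead

    n_ch = len(montage.channels)
    signal = _pink_noise(
        rng, (n_ch,), n, fs, cfg.noise_exponent, cfg.background_rms
    )
    sources = rng.standard_normal((cfg.n_shared_sources, n))
    signal += (mixing @ sources) * cfg.shared_noise_rms

    # narrowband Mu rhythm on the sensorimotor line, with per-trial
    # contralateral envelope attenuation (the planted ERD)
    depth = cfg.erd_depth[session_index]
    mu_channels = {"C3": 1.0, "C4": 1.0, "Cz": 0.5}
    envelopes = {
        ch: np.ones(n) for ch in ("C3", "C4") if depth > 0
    }
    ramp = max(1, int(round(0.025 * fs)))
    for onset, label in zip(onsets, labels):
        if label == "hold" or depth == 0:
            continue
        contra = montage.contralateral(label)
        if contra not in envelopes:
            continue
        env = envelopes[contra]
        factor = 1.0 - depth
        seg = np.full(na, factor)
        seg[:ramp] = np.linspace(1.0, factor, ramp)
        seg[-ramp:] = np.linspace(factor, 1.0, ramp)
        env[onset : onset + na] = seg
    for ch, gain in mu_channels.items():
        raw = sps.sosfiltfilt(sos_mu, rng.standard_normal(n))
        raw = raw / raw.std() * cfg.mu_rms * gain
        idx = montage.index(ch)
        if ch in envelopes:
            raw = raw * envelopes[ch]
        signal[idx] += raw

    # stereotyped ERP on non-hold action windows
    template = _erp_template(cfg)
    weights = _spatial_weights(montage)
    g = cfg.shared_gain[session_index]
    for onset, label in zip(onsets, labels):
        if label == "hold":
            continue
        jitter = 1.0 + cfg.erp_gain_jitter * rng.standard_normal(n_ch)
        gains = g * weights * jitter
        signal[:, onset : onset + na] += gains[:, None] * template[None, :]

    return SessionRecord(signal, tuple(onsets), tuple(labels))


def simulate_sessions(cfg: SimulationConfig) -> list[SessionRecord]:
    """Continuous per-session records (the unit written to EDF)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    montage = standard_montage()
    mixing = rng.standard_normal((len(montage.channels), cfg.n_shared_sources))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    sos_mu = sps.butter(4, cfg.mu_band, btype="bandpass", fs=cfg.sampling_rate,
                        output="sos")
    return [
        _simulate_session(cfg, rng, s, montage, mixing, sos_mu)
        for s in range(cfg.n_sessions)
    ]


def epoch_sessions(
    cfg: SimulationConfig, records: list[SessionRecord]
) -> EpochedRecording:
    """Cut [-1, +1] s epochs around every action onset."""
    fs = cfg.sampling_rate
    half = int(round(fs))
    times = np.arange(-half, half + 1) / fs
    epochs, rows = [], []
    trial_counter = 0
    for s, rec in enumerate(records):
        for onset, label in zip(rec.onset_samples, rec.labels):
            epochs.append(rec.signal[:, onset - half : onset + half + 1])
            rows.append(
                {"trial": trial_counter, "task": label, "session": s + 1,
                 "day": cfg.day}
            )
            trial_counter += 1
    return EpochedRecording(
        data=np.stack(epochs),
        sampling_rate=fs,
        times=times,
        meta=pd.DataFrame(rows),
    )


def generate_recording(cfg: SimulationConfig) -> tuple[EpochedRecording, GroundTruth]:
    """Simulate the full paradigm and return epochs plus planted truth."""
    records = simulate_sessions(cfg)
    rec = epoch_sessions(cfg, records)
    truth = GroundTruth(
        erd_depth=tuple(cfg.erd_depth),
        shared_gain=tuple(cfg.shared_gain),
        mu_band=cfg.mu_band,
        labels=tuple(r.labels for r in records),
        onset_samples=tuple(r.onset_samples for r in records),
    )
    return rec, truth


# profiles for the two emulated training conditions -----------------------

FEEDBACK_ERD = (0.2, 0.4, 0.6)
FEEDBACK_GAIN = (1.0, 0.8, 0.6)
NONFEEDBACK_ERD = (0.4, 0.4, 0.4)
NONFEEDBACK_GAIN = (1.0, 1.0, 1.0)


def condition_config(cfg: SimulationConfig, condition: str) -> SimulationConfig:
    """Config for the 'feedback' (trending) or 'nonfeedback' (flat) fixture."""
    n = cfg.n_sessions

    def _stretch(profile):
        return tuple(np.interp(np.linspace(0, 1, n), np.linspace(0, 1, 3), profile))

    if condition == "feedback":
        return cfg.with_profiles(_stretch(FEEDBACK_ERD), _stretch(FEEDBACK_GAIN))
    if condition == "nonfeedback":
        return cfg.with_profiles(_stretch(NONFEEDBACK_ERD), _stretch(NONFEEDBACK_GAIN))
    raise ConfigurationError(f"unknown condition {condition!r}")


class ConditionPair(NamedTuple):
    feedback: tuple[EpochedRecording, GroundTruth]
    nonfeedback: tuple[EpochedRecording, GroundTruth]


def generate_condition_pair(cfg: SimulationConfig) -> ConditionPair:
    """Matched feedback / non-feedback fixtures differing only in trends.

    The feedback member has strictly increasing ERD depth and strictly
    decreasing shared ERP gain across sessions; the non-feedback member
    has constant profiles.  The non-feedback seed is offset so the two
    recordings are independent draws.
    """
    fb_cfg = condition_config(cfg, "feedback")
    nf_cfg = replace(condition_config(cfg, "nonfeedback"), seed=cfg.seed + 1_000_003)
    return ConditionPair(generate_recording(fb_cfg), generate_recording(nf_cfg))
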
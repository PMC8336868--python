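"""Filtering and trial-block construction."""

import numpy as np
import pandas as pd
import pytest

from mipipe.errors import ConfigurationError
from mipipe.preprocessing import (
    ANALYSIS_BAND,
    BandDefinition,
    FIVE_BAND_GRID,
    bandpass,
    day_synchronize,
    make_trial_blocks,
)
from mipipe.recording import EpochedRecording


def _sine_recording(freq, fs=200.0, n_trials=1, amplitude=1.0):
    times = np.arange(-int(fs), int(fs) + 1) / fs
    wave = amplitude * np.sin(2 * np.pi * freq * times)
    data = np.tile(wave, (n_trials, 19, 1))
    meta = pd.DataFrame({"trial": range(n_trials),
                         "task": ["left"] * n_trials,
                         "session": [1] * n_trials, "day": [1] * n_trials})
    return EpochedRecording(data=data, sampling_rate=fs, times=times, meta=meta)


def test_inband_sinusoid_amplitude_preserved():
    rec = _sine_recording(10.0)
    out = bandpass(rec, ANALYSIS_BAND)
    core = (rec.times > -0.7) & (rec.times < 0.7)  # away from epoch edges
    ratio = np.abs(out.data[0, 0, core]).max() / np.abs(rec.data[0, 0, core]).max()
    assert ratio == pytest.approx(1.0, abs=0.02)


def test_stopband_sinusoid_attenuated_20db():
    rec = _sine_recording(1.0)
    out = bandpass(rec, ANALYSIS_BAND)
    core = (rec.times > -0.7) & (rec.times < 0.7)
    in_rms = np.sqrt(np.mean(rec.data[0, 0, core] ** 2))
    out_rms = np.sqrt(np.mean(out.data[0, 0, core] ** 2))
    assert 20 * np.log10(in_rms / out_rms) >= 20.0


def test_zero_signal_stays_zero():
    rec = _sine_recording(10.0, amplitude=0.0)
    out = bandpass(rec, ANALYSIS_BAND)
    assert np.allclose(out.data, 0.0)


def test_filter_idempotent_for_inband_signal():
    rec = _sine_recording(10.0)
    once = bandpass(rec, ANALYSIS_BAND)
    twice = bandpass(once, ANALYSIS_BAND)
    core = (rec.times > -0.7) & (rec.times < 0.7)
    ratio = (np.abs(twice.data[0, 0, core]).max()
             / np.abs(once.data[0, 0, core]).max())
    assert ratio == pytest.approx(1.0, abs=0.02)


def test_band_violating_nyquist_rejected():
    rec = _sine_recording(10.0, fs=50.0)
    with pytest.raises(ConfigurationError):
        bandpass(rec, BandDefinition(3.0, 30.0))


def test_band_grid_contents():
    labels = [b.label() for b in FIVE_BAND_GRID]
    assert labels == ["0.53-4Hz", "3-6Hz", "5-10Hz", "8-16Hz", "15-30Hz"]
    with pytest.raises(ConfigurationError):
        BandDefinition(6.0, 3.0)


def _stacked_recording(datas, tasks, sessions=None, fs=200.0):
    n = len(datas)
    times = np.arange(-int(fs), int(fs) + 1) / fs
    meta = pd.DataFrame({"trial": range(n), "task": tasks,
                         "session": sessions or [1] * n, "day": [1] * n})
    return EpochedRecording(data=np.stack(datas), sampling_rate=fs,
                            times=times, meta=meta)


def test_block_chunking_drops_trailing_partial():
    rng = np.random.default_rng(0)
    datas = [rng.standard_normal((19, 401)) for _ in range(45)]
    rec = _stacked_recording(datas, ["left"] * 45)
    blocks = make_trial_blocks(rec, block_size=20)
    assert len(blocks) == 2
    assert all(b.n_trials == 20 for b in blocks)


def test_block_count_formula_over_groups():
    rng = np.random.default_rng(1)
    tasks = ["left"] * 47 + ["right"] * 23
    datas = [rng.standard_normal((19, 401)) for _ in tasks]
    rec = _stacked_recording(datas, tasks)
    blocks = make_trial_blocks(rec, block_size=20)
    assert len(blocks) == 47 // 20 + 23 // 20


def test_block_of_identical_trials_equals_template():
    template = np.random.default_rng(2).standard_normal((19, 401))
    rec = _stacked_recording([template] * 20, ["left"] * 20)
    blocks = make_trial_blocks(rec, block_size=20)
    # identical up to the last-ulp rounding of the running mean
    assert np.allclose(blocks[0].data, template, rtol=1e-14, atol=0)


def test_block_noise_reduction_follows_sqrt_n():
    """Mean of 20 noisy copies of a template has residual sd ~ 1/sqrt(20)."""
    rng = np.random.default_rng(3)
    template = rng.standard_normal((19, 401))
    datas = [template + rng.standard_normal((19, 401)) for _ in range(20)]
    rec = _stacked_recording(datas, ["left"] * 20)
    block = make_trial_blocks(rec, block_size=20)[0]
    residual_sd = (block.data - template).std()
    assert residual_sd == pytest.approx(1 / np.sqrt(20), rel=0.15)


def test_blocks_commute_with_channel_permutation():
    rng = np.random.default_rng(4)
    datas = [rng.standard_normal((19, 401)) for _ in range(20)]
    rec = _stacked_recording(datas, ["left"] * 20)
    perm = rng.permutation(19)
    rec_perm = EpochedRecording(data=rec.data[:, perm, :],
                                sampling_rate=rec.sampling_rate,
                                times=rec.times, meta=rec.meta)
    direct = make_trial_blocks(rec, 20)[0].data[perm, :]
    permuted = make_trial_blocks(rec_perm, 20)[0].data
    assert np.array_equal(direct, permuted)


def test_blocks_never_span_sessions_or_tasks():
    rng = np.random.default_rng(5)
    tasks = (["left"] * 15 + ["right"] * 15) * 2
    sessions = [1] * 30 + [2] * 30
    datas = [rng.standard_normal((19, 401)) for _ in tasks]
    rec = _stacked_recording(datas, tasks, sessions)
    blocks = make_trial_blocks(rec, block_size=10)
    assert len(blocks) == 4  # one per (session, task) of 15 trials
    assert {(b.session, b.task_label) for b in blocks} == {
        (1, "left"), (1, "right"), (2, "left"), (2, "right")}


def test_block_size_below_two_rejected(toy_recording):
    with pytest.raises(ConfigurationError):
        make_trial_blocks(toy_recording, block_size=1)


@pytest.mark.parametrize(
    "series, expected",
    [
        ({1: [1, 2, 3], 2: [3, 2, 1]}, [2, 2, 2]),
        ({1: [5, 6, 7]}, [5, 6, 7]),
        ({1: list(range(10)), 2: list(range(8))},
         list(np.mean([range(8), range(8)], axis=0))),
    ],
)
def test_day_synchronize_trims_and_averages(series, expected):
    out = day_synchronize({k: np.asarray(v, float) for k, v in series.items()})
    assert np.allclose(out, expected)
    assert len(out) == min(len(v) for v in series.values())
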
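"""Replicated simulation experiments: recovery, calibration, power.

These are the package's self-validation studies, run both by the test
suite and by ``scripts/acceptance.py``:

* **Band recovery** — can the sliding-window screening find a planted
  9-12 Hz suppression?  (many independent seeds, hit = selected window
  within 1 Hz of the truth).
* **Null calibration** — under the flat (non-feedback) generator, does
  the session-1 vs session-3 Welch test on mean node degree reject at
  its nominal rate?
* **Trend power** — does the feedback profile (increasing ERD depth,
  decreasing shared ERP gain) produce a significant session-3 degree
  drop and a positive Mu-suppression slope, while the flat profile stays
  quiet?

Replicates use a reduced per-run problem size (fewer trials per session
than the full 300-trial protocol) so hundreds of end-to-end runs stay
cheap; 240 trials/session still yields 8 ERP blocks per session, enough
for stable block statistics.  Every replicate derives its seed from
``base_seed`` deterministically.
"""

from __future__ import annotations

from scipy.stats import binom

from .mu import musc_series, select_mu_band
from .network import metrics_table
from .preprocessing import ANALYSIS_BAND, bandpass, make_trial_blocks
from .recording import EpochedRecording, select_trials
from .stats import ComparisonResult, compare_supertrials, fit_slope
from .synthetic import SimulationConfig, condition_config, generate_recording

#: trials per session used by replicated experiments (8 blocks/session)
REPLICATE_TRIALS = 240
#: trials in the single-session band-recovery screening runs
SCREENING_TRIALS = 60


def _replicate_seed(base_seed: int, index: int) -> int:
    return (int(base_seed) * 1_000_000 + index) % (2**31 - 1)


def degree_session_comparison(rec: EpochedRecording, block_size: int = 20
                              ) -> ComparisonResult:
    """Welch test of task-window mean node degree, session 1 vs session 3."""
    nonhold = select_trials(rec, tasks=("left", "right"))
    filtered = bandpass(nonhold, ANALYSIS_BAND)
    blocks = make_trial_blocks(filtered, block_size)
    table = metrics_table(blocks)
    series = table[(table["window_role"] == "task")
                   & (table["indicator"] == "mean_degree")]
    results = compare_supertrials(series, indicator="mean_degree",
                                  pairs=((1, 3),))
    return results[0]


def musc_contra_slope(rec: EpochedRecording, block_size: int = 20) -> float:
    """OLS slope of the contralateral MuSC block series."""
    nonhold = select_trials(rec, tasks=("left", "right"))
    selection = select_mu_band(nonhold)
    series = musc_series(nonhold, selection, block_size=block_size)
    contra = series[series["channel_role"] == "contra"].sort_values("block")
    return fit_slope(contra["musc"].to_numpy()).slope


def band_recovery_experiment(n_seeds: int = 100, base_seed: int = 0,
                             depth: float = 0.5,
                             true_band: tuple[float, float] = (9.0, 12.0)
                             ) -> dict:
    """Fraction of seeds whose selected window lands within 1 Hz of truth."""
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=_replicate_seed(base_seed, i),
                               n_sessions=1,
                               trials_per_session=SCREENING_TRIALS,
                               erd_depth=(depth,))
        rec, _ = generate_recording(cfg)
        sel = select_mu_band(select_trials(rec, tasks=("left", "right")))
        if abs(sel.lo - true_band[0]) <= 1.0 and abs(sel.hi - true_band[1]) <= 1.0:
            hits += 1
    return {"rate": hits / n_seeds, "hits": hits, "n_seeds": n_seeds,
            "trials_per_run": SCREENING_TRIALS}


def null_calibration_experiment(n_reps: int = 200, base_seed: int = 0,
                                alpha: float = 0.05) -> dict:
    """Rejection rate of the 1-vs-3 degree test under the flat generator.

    Also reports the exact central binomial 95% acceptance interval for
    ``n_reps`` trials at probability ``alpha``.
    """
    rejections = 0
    for i in range(n_reps):
        cfg = condition_config(
            SimulationConfig(seed=_replicate_seed(base_seed, i),
                             trials_per_session=REPLICATE_TRIALS),
            "nonfeedback")
        rec, _ = generate_recording(cfg)
        if degree_session_comparison(rec).p < alpha:
            rejections += 1
    lo, hi = binom.interval(0.95, n_reps, alpha)
    return {"rate": rejections / n_reps, "rejections": rejections,
            "n_reps": n_reps, "alpha": alpha,
            "interval_lo": lo / n_reps, "interval_hi": hi / n_reps,
            "trials_per_run": REPLICATE_TRIALS}


def trend_power_experiment(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Power/stability of the feedback vs non-feedback contrast.

    Feedback replicates count as detected when the session-3 mean node
    degree is significantly *lower* than session 1 at p < 0.01; their
    MuSC slope counts as recovered when positive.  Non-feedback
    replicates count as stable when the same degree test stays above
    p = 0.05.
    """
    fb_detected = fb_musc_positive = nf_stable = 0
    for i in range(n_seeds):
        seed = _replicate_seed(base_seed, i)
        fb_cfg = condition_config(
            SimulationConfig(seed=seed, trials_per_session=REPLICATE_TRIALS),
            "feedback")
        fb_rec, _ = generate_recording(fb_cfg)
        comp = degree_session_comparison(fb_rec)
        if comp.p < 0.01 and comp.mean_b < comp.mean_a:
            fb_detected += 1
        if musc_contra_slope(fb_rec) > 0:
            fb_musc_positive += 1

        nf_cfg = condition_config(
            SimulationConfig(seed=seed + 7_654_321,
                             trials_per_session=REPLICATE_TRIALS),
            "nonfeedback")
        nf_rec, _ = generate_recording(nf_cfg)
        if degree_session_comparison(nf_rec).p >= 0.05:
            nf_stable += 1
    return {
        "n_seeds": n_seeds,
        "feedback_degree_drop_rate": fb_detected / n_seeds,
        "feedback_musc_positive_slope_rate": fb_musc_positive / n_seeds,
        "nonfeedback_stable_rate": nf_stable / n_seeds,
        "trials_per_run": REPLICATE_TRIALS,
    }
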
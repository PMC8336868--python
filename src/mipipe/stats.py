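"""Super-trial statistics and end-to-end pipeline orchestration.

Sessions act as *super-trials*: blocks inside each session form the
samples for pairwise between-session comparisons (Welch's unequal-
variance t-test, two-sided), and block series over the whole course are
summarized by an ordinary-least-squares slope.  ``run_pipeline`` wires
the full analysis (load/simulate -> select -> filter -> Mu branch +
network branch -> statistics) and writes tidy CSVs, a JSON summary and a
run log; with deterministic inputs a re-run is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from . import io as mio
from .errors import ConfigurationError, PipelineError
from .mu import musc_series, select_mu_band
from .network import DEFAULT_THRESHOLD, band_scan_degree, metrics_table
from .preprocessing import ANALYSIS_BAND, BandDefinition, bandpass, make_trial_blocks
from .recording import EpochedRecording, select_trials
from .synthetic import SimulationConfig, condition_config, generate_recording

logger = logging.getLogger(__name__)

SUPER_TRIAL_PAIRS = ((1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided t-test between two super-trials of one indicator."""

    indicator: str
    group_a: int
    group_b: int
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    significant_05: bool
    significant_01: bool


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of a block series against its 1-based block index."""

    series_id: str
    slope: float
    intercept: float
    stderr: float
    n: int


def welch_t_test(group_a, group_b, indicator: str = "",
                 groups: tuple[int, int] = (0, 0),
                 variant: str = "welch") -> ComparisonResult:
    """Welch's (default) or Student's pooled two-sided t-test.

    Degenerate input — both groups constant with equal means — yields
    t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs at least 2 values")
    if variant not in ("welch", "student"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        t, p = spstats.ttest_ind(a, b, equal_var=(variant == "student"))
        t, p = float(t), float(p)
    return ComparisonResult(
        indicator=indicator, group_a=groups[0], group_b=groups[1],
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        t=t, p=p, significant_05=bool(p < 0.05), significant_01=bool(p < 0.01),
    )


def fit_slope(values, series_id: str = "") -> TrendFit:
    """OLS of value on 1-based block index."""
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise ConfigurationError("trend fit needs at least 3 points")
    x = np.arange(1, y.size + 1, dtype=float)
    res = spstats.linregress(x, y)
    return TrendFit(series_id=series_id, slope=float(res.slope),
                    intercept=float(res.intercept),
                    stderr=float(res.stderr), n=int(y.size))


def supertrial_of(session: int, mapping: dict[int, int] | None = None) -> int:
    """Session -> super-trial; identity unless an override mapping is given."""
    if mapping is None:
        return int(session)
    return int(mapping[int(session)])


def compare_supertrials(frame: pd.DataFrame, value_col: str = "value",
                        group_col: str = "session", indicator: str = "",
                        pairs=SUPER_TRIAL_PAIRS,
                        variant: str = "welch") -> list[ComparisonResult]:
    """All pairwise super-trial comparisons available in ``frame``."""
    results = []
    groups = {int(g): grp[value_col].to_numpy()
              for g, grp in frame.groupby(group_col)}
    for a, b in pairs:
        if a in groups and b in groups and len(groups[a]) >= 2 and len(groups[b]) >= 2:
            results.append(
                welch_t_test(groups[a], groups[b], indicator=indicator,
                             groups=(a, b), variant=variant)
            )
    return results


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparisons; adds a BH-adjusted p column (extension)."""
    frame = pd.DataFrame([asdict(r) for r in results])
    if len(frame):
        frame["p_bh"] = multipletests(frame["p"].to_numpy(),
                                      method="fdr_bh")[1]
    return frame


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_ANALYSIS = {
    "band": [ANALYSIS_BAND.lo, ANALYSIS_BAND.hi],
    "block_size": 20,
    "threshold": DEFAULT_THRESHOLD,
    "mu_search": [5.0, 20.0],
    "mu_width": 3.0,
    "mu_overlap": 0.67,
    "t_test": "welch",
    "band_scan": False,
    "use_absolute": False,
}

_NETWORK_INDICATORS = ("mean_degree", "mean_target_degree", "lnl", "lnr", "ex",
                       "clustering_all", "clustering_left", "clustering_right")


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def load_input(config: dict) -> EpochedRecording:
    """Resolve the pipeline input: simulation, epochs table, or EDF set."""
    spec = config.get("input")
    if not spec or "kind" not in spec:
        raise ConfigurationError("config['input']['kind'] is required")
    kind = spec["kind"]
    if kind == "simulation":
        sim_kwargs = dict(spec.get("simulation", {}))
        cfg = SimulationConfig(**sim_kwargs)
        condition = spec.get("condition")
        if condition:
            cfg = condition_config(cfg, condition)
        if "seed" in spec:
            cfg = SimulationConfig(**{**cfg.__dict__, "seed": int(spec["seed"])})
        rec, _ = generate_recording(cfg)
        return rec
    if kind == "epochs_table":
        return mio.read_epochs_table(spec["path"])
    if kind == "edf":
        from .recording import concat_recordings

        entries = spec["files"]  # list of {path, events}
        recs = []
        for entry in entries:
            events = mio.read_events_csv(entry["events"])
            recs.append(mio.read_edf(entry["path"], events))
        return concat_recordings(recs)
    raise ConfigurationError(f"unknown input kind {kind!r}")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full analysis and (optionally) write the report bundle.

    Returns the summary dictionary; when ``out_dir`` is given, writes
    ``metrics.csv``, ``musc.csv``, ``comparisons.csv``, ``trends.csv``,
    ``band_selection.json``, ``summary.json`` and ``run.log`` there.
    """
    analysis = {**DEFAULT_ANALYSIS, **config.get("analysis", {})}

    with _stage("load"):
        rec = load_input(config)
    with _stage("select"):
        nonhold = select_trials(rec, tasks=("left", "right"))
    with _stage("filter"):
        band = BandDefinition(*analysis["band"], "analysis")
        filtered = bandpass(nonhold, band)

    # --- Mu-suppression branch (per day band selection) -----------------
    with _stage("mu_band_selection"):
        selections = {}
        for day in sorted(nonhold.meta["day"].unique()):
            day_rec = select_trials(nonhold, days=(day,))
            selections[int(day)] = select_mu_band(
                day_rec, search_range=tuple(analysis["mu_search"]),
                width=analysis["mu_width"], overlap=analysis["mu_overlap"],
            )
    with _stage("musc_series"):
        musc_parts = []
        for day, sel in selections.items():
            day_rec = select_trials(nonhold, days=(day,))
            musc_parts.append(
                musc_series(day_rec, sel, block_size=analysis["block_size"])
            )
        musc = pd.concat(musc_parts, ignore_index=True)
    with _stage("musc_statistics"):
        contra = musc[musc["channel_role"] == "contra"].sort_values(
            ["day", "block"])
        musc_trend = fit_slope(
            contra.groupby("block")["musc"].mean().to_numpy(),
            series_id="musc_contra",
        )
        musc_comparisons = compare_supertrials(
            contra, value_col="musc", indicator="musc_contra",
            variant=analysis["t_test"],
        )

    # --- network branch --------------------------------------------------
    with _stage("trial_blocks"):
        blocks = make_trial_blocks(filtered, analysis["block_size"])
    with _stage("network_metrics"):
        metrics = metrics_table(blocks, threshold=analysis["threshold"],
                                use_absolute=analysis["use_absolute"])
    with _stage("network_statistics"):
        comparisons = list(musc_comparisons)
        trends = [musc_trend]
        task_metrics = metrics[metrics["window_role"] == "task"]
        for window_role in ("task", "rest"):
            sub = metrics[metrics["window_role"] == window_role]
            for indicator in _NETWORK_INDICATORS:
                series = sub[sub["indicator"] == indicator]
                comparisons.extend(
                    compare_supertrials(
                        series, indicator=f"{indicator}_{window_role}",
                        variant=analysis["t_test"])
                )
        for indicator in _NETWORK_INDICATORS:
            series = task_metrics[task_metrics["indicator"] == indicator]
            ordered = series.sort_values(["day", "start_trial"])
            trends.append(fit_slope(ordered["value"].to_numpy(),
                                    series_id=f"{indicator}_task"))
    scan = None
    if analysis["band_scan"]:
        with _stage("band_scan"):
            scan = band_scan_degree(rec, block_size=analysis["block_size"])

    with _stage("report"):
        comp_frame = comparisons_frame(comparisons)
        trend_frame = pd.DataFrame([asdict(t) for t in trends])
        summary = {
            "n_trials": int(rec.n_trials),
            "n_nonhold_trials": int(nonhold.n_trials),
            "n_blocks": int(len(blocks)),
            "analysis": analysis,
            "mu_band_by_day": {
                str(day): {"lo": sel.lo, "hi": sel.hi, "score": sel.score}
                for day, sel in selections.items()
            },
            "trends": {t.series_id: {"slope": t.slope,
                                     "intercept": t.intercept,
                                     "stderr": t.stderr, "n": t.n}
                       for t in trends},
            "comparisons": [
                {k: (v if not isinstance(v, (np.floating, np.bool_))
                     else v.item())
                 for k, v in row.items()}
                for row in comp_frame.to_dict(orient="records")
            ],
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        musc.to_csv(out / "musc.csv", index=False)
        comp_frame.to_csv(out / "comparisons.csv", index=False)
        trend_frame.to_csv(out / "trends.csv", index=False)
        if scan is not None:
            scan.to_csv(out / "band_scan.csv", index=False)
        band_report = {
            str(day): {"lo": sel.lo, "hi": sel.hi, "score": sel.score,
                       "table": sel.table.to_dict(orient="records")}
            for day, sel in selections.items()
        }
        (out / "band_selection.json").write_text(
            json.dumps(band_report, indent=2, sort_keys=True))
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        log_lines = [f"analysis.{k} = {v}" for k, v in sorted(analysis.items())]
        log_lines += [f"input.{k} = {v}"
                      for k, v in sorted(config.get("input", {}).items())]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
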
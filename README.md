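# mipipe

Assessment pipeline for **short-term motor-imagery BCI training** from
19-channel 10-20 EEG. Given epoched left/right/hold grasp-imagery trials
(or its own synthetic recordings), the package quantifies two
complementary signatures of a training session sequence:

1. **Mu suppression (ERD).** Event-related desynchronization attenuates
   the sensorimotor Mu rhythm contralateral to the imagined hand. The
   Mu-suppression score compares multitaper band power of the 1-s action
   window against the most recent resting second,

       MuSC = -100 · (MuP_bo − MuP_nbo) / MuP_nbo

   (bo = task state, nbo = resting state; positive = suppression), with
   the subject- and day-specific Mu band chosen by sliding a 3-Hz window
   (0.67 overlap) over 5–20 Hz and keeping the most suppressed window.

2. **ERP brain networks.** Twenty consecutive same-task trials are
   averaged into a *trial-block* ERP (3–30 Hz, zero-phase band-pass);
   Pearson correlation between channels builds a weighted graph per
   block, read at three scales:
   node degree `E_i(G) = Σ_{j≠i} d_ij`; regional degree (left/right
   hemisphere sums `LnL`, `LnR`, and the cross-hemisphere sum `EX`
   excluding the midline); and global transitivity
   `C = 3·G_Δ / (3·G_Δ + G_Λ)` on the graph binarized at ρ ≥ 0.6.

Sessions act as *super-trials*: blocks within each session are compared
across sessions with Welch's t-test, and block series are summarized by
OLS slopes — the statistics used to contrast training **with** visual
feedback (trending) against training **without** it (flat).

The `mipipe.synthetic` module generates the full paradigm (3 sessions ×
300 trials, 1.5–2.5 s pauses + 1-s actions, planted contralateral ERD,
stereotyped ERP deflections at 0.35/0.55/0.65 s, spatially correlated
1/f background) with known ground truth, so every stage is testable
against planted parameters. See `docs/methods.md` for the model details.

## Worked example

```sh
mipipe simulate --out data --condition feedback --seed 11 --format both
mipipe musc --in data/epochs.csv --out musc.csv --band-report band.json
```

prints

```
wrote 3 session(s) to data
selected Mu band 9-12 Hz (mean MuSC 51.87); wrote musc.csv
```

The screening found the planted 9–12 Hz Mu band; the mean score of
51.9 says task-window Mu power is roughly half the resting power across
this recording's trials (the feedback profile plants ERD depths
0.2/0.4/0.6 over the three sessions). The full pipeline runs from a
YAML config:

```yaml
# run.yaml
input:
  kind: simulation        # or epochs_table / edf
  condition: feedback
  seed: 11
```

```sh
mipipe run --config run.yaml --out out
```

```json
{
  "trend_slopes": {
    "clustering_all_task": -0.0187,
    "clustering_left_task": -0.0101,
    "clustering_right_task": -0.0098,
    "ex_task": -0.6281,
    "lnl_task": -0.2784,
    "lnr_task": -0.267,
    "mean_degree_task": -0.1811,
    "mean_target_degree_task": -0.1855,
    "musc_contra": 1.4627
  }
}
```

Negative network slopes (degree, regional degree, clustering all
declining over blocks) together with a rising MuSC series are the
feedback-training signature; `out/` holds the tidy block metrics,
all pairwise super-trial comparisons (with t, p, and BH-adjusted p),
trend fits, the band-selection table, and a `summary.json` that is
byte-identical across re-runs of the same config.

File formats (epochs table, events CSV, EDF) are documented in
`mipipe/io.py`; the epochs table is a `#`-headered CSV with columns
`trial,channel,sample_index,value`, events CSVs carry
`trial_index,session,day,task_label,onset_sample`.

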
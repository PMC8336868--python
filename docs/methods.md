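# Methods

## The analysis model

The pipeline treats a short motor-imagery (MI) BCI training course —
three sessions of cued left/right/hold grasp-imagery trials recorded on
a 19-channel 10-20 montage — as a sequence of *super-trials* (the
sessions) and asks whether two electrophysiological signatures change
across them.

**Mu suppression.** Each trial contributes a 1-s action window
([0, 1) s from cue onset) and its immediately preceding resting second
([-1, 0) s). Band power in the subject's Mu band is estimated with a
multitaper PSD and the suppression score is

    MuSC = -100 · (P_task − P_rest) / P_rest

at the channel contralateral to the imagined hand (C4 for left-hand MI,
C3 for right-hand MI; the ipsilateral mirror is computed alongside).
Positive MuSC means task-related power attenuation (ERD). Because Mu
boundaries are subject- and day-specific, a 3-Hz window slides across
5–20 Hz (nominal step 3 Hz × (1 − 0.67) = 0.99 Hz, snapped to 1 Hz to
align with the 1-Hz PSD grid of a 1-s segment, giving 13 candidate
windows [5, 8] … [17, 20]); the window with the largest mean
suppression over that day's non-hold trials is the selected band, ties
resolved toward the lowest frequencies.

**ERP networks.** Non-hold trials are band-passed to 3–30 Hz, and
twenty consecutive same-task trials within a session are averaged into
one *trial-block* ERP. Pearson correlation between the 19 channels over
an analysis window (task [0, 1) s; rest [-1, 0) s as control) defines a
weighted graph per block with signed edge weights d_ij = ρ_ij. Three
indicator scales:

* node degree `E_i = Σ_{j≠i} d_ij` (weighted, signed);
* regional degree: within-hemisphere edge-weight sums LnL/LnR over the
  8-channel lateral sets, and the cross-hemisphere sum EX over
  left × right pairs, with the midline (Fz, Cz, Pz) excluded from all
  three;
* global transitivity `3·G_Δ / (3·G_Δ + G_Λ)` (triangles vs connected
  triples, integer-exact) on the graph binarized at ρ ≥ 0.6. The
  comparison is signed — strongly negative correlations do not create
  edges — with `use_absolute` exposed as a config flag.

**Statistics.** Blocks within a session are the samples for pairwise
super-trial comparisons (1–2, 1–3, 2–3) with Welch's two-sided t-test
(Student's pooled variant available as a config switch); block series
are summarized by OLS slope on the 1-based block index. Raw p-values
are reported; a Benjamini–Hochberg-adjusted column is added for
transparency as a clearly labelled extension, not used by any decision
in the pipeline.

## Numerical choices

* **Multitaper settings**: 1-s windows, DPSS tapers with time-bandwidth
  NW = 2 and 3 tapers, eigenvalue-weighted, one-sided density scaling
  (integrated PSD ≈ variance). This targets ≈ 3 Hz spectral resolution,
  matching the 3-Hz selection windows. Band power is the mean PSD over
  bins with lo ≤ f ≤ hi inclusive.
* **Aggregation order of the score**: a single 1-s multitaper band
  power has only a few effective degrees of freedom, so the expectation
  of a per-trial power *ratio* is noticeably biased (E[1/P_rest] >
  1/E[P_rest]; empirically ≈ −45 score points on null data). The
  package therefore averages task and rest powers across a block's 20
  trials (or across all screening trials during band selection) and
  applies the score once; the residual bias is ≈ −1.5 points.
* **Filtering**: zero-phase forward-backward 4th-order Butterworth
  band-pass per 2-s epoch with 0.5 s reflection padding. Zero phase
  preserves the ERP deflection latencies (0.35/0.55/0.65 s) that the
  analysis interprets; epoch-wise filtering (rather than continuous) is
  a deliberate simplification.
* **Trial blocks**: chunks never span sessions, days or task labels;
  trailing partial chunks are dropped so every block averages exactly 20
  trials (homogeneous noise level). The pooled Mu-score series instead
  chunks consecutive non-hold trials regardless of side, each trial
  scored at its own contralateral channel, because that series mirrors a
  course-long pooled trend rather than per-side networks.
* **Degenerate inputs**: channels whose analysis window is numerically
  constant (std below 1e-12 of the amplitude scale) get zero-weight
  edges with a logged warning instead of NaNs; a t-test between two
  constant equal groups returns t = 0, p = 1; transitivity of a graph
  with no connected triple is 0.

## The synthetic paradigm

`mipipe.synthetic` emulates the study conditions the analysis assumes,
per session and channel (microvolts):

    x(t) = pink(t) + M s(t) + mu(t)·env(t) + g_s · w_c · ERP(t − onset)

* 3 sessions × 300 trials (configurable), pauses uniform 1.5–2.5 s,
  1-s actions, equal left/right/hold mix (largest-remainder rounding),
  200 Hz sampling (a typical clinical-recorder rate; the protocol
  itself does not fix one), epochs cut at [-1, +1] s (401 samples).
* **Background**: per-channel 1/f noise (exponent 1, 9 µV rms) plus
  K = 4 shared broadband sources mixed through a fixed random matrix
  (6 µV rms per channel), planting non-trivial baseline inter-channel
  correlation.
* **Mu rhythm**: 9–12 Hz narrowband noise at C3 and C4 (6 µV rms, Cz at
  half amplitude). During a left (right) MI action the C4 (C3) envelope
  is multiplied by 1 − erd_depth[session] with 25-ms linear ramps —
  ERD as task-locked multiplicative amplitude attenuation.
* **ERP**: three Gaussian-windowed deflections (σ = 40 ms) at
  0.35/0.55/0.65 s with signs (−, +, −) and default amplitudes
  (−8, 12, −8) µV, spatial weight 0.3 + 0.7·exp(−d²/0.36) by squared
  grid distance d² from the vertex, scaled by the per-session
  shared_gain and ≈10% per-channel gain jitter. Hold trials receive
  neither ERP nor ERD.
* **Trend profiles**: the *feedback* condition plants erd_depth
  (0.2, 0.4, 0.6) and shared_gain (1.0, 0.8, 0.6) across sessions; the
  *non-feedback* condition keeps both flat at (0.4, 0.4, 0.4) and
  (1.0, 1.0, 1.0). Session-indexed vectors (not per-trial drift) match
  the super-trial resolution of the statistics.
* One seeded generator drives every draw; identical configs are
  bit-identical.

Amplitudes were chosen from an SNR budget: the Mu rhythm concentrates
≈ 36 µV² into a 3-Hz band against ≈ 6 µV² of in-band background, so a
planted depth d maps to an expected score near
100·(1 − ((1−d)²·36 + 6)/42), ≈ 52 at d = 0.4; and after 20-trial
averaging the ERP variance in 3–30 Hz (≈ 19 µV² centrally at gain 1)
dominates the ≈ 2 µV² residual noise, placing central task-window
correlations around 0.7 at gain 1.0 and 0.5 at gain 0.6 — i.e. the 0.6
binarization threshold bites inside the planted gain range.

**What the generator does not emulate**: eye-blink/EMG artifacts,
electrode pops, re-referencing, volume-conduction field spread, alpha
non-stationarity, or a closed-loop decoder. Rest-window graphs at the
0.6 threshold are consequently near-empty (baseline correlations peak
≈ 0.25), so rest-state comparisons are quiet by construction. Passing
tests therefore demonstrate correctness of the estimators and
statistics under the planted model, not robustness to real-EEG
artifacts. A further known coupling: the ERP template's deflection
spacing (0.1–0.2 s) puts genuine power into the alpha band, so the
task window of ERP-bearing channels carries a small score offset that
tracks shared_gain; it does not affect the flat (null) profiles.

## Validation experiments and problem sizes

The replicated studies (in `mipipe.experiments`, used by both the test
suite and `scripts/acceptance.py`) run many end-to-end replicates, so
each replicate uses a reduced layout chosen up front: band-recovery
screening uses 1 session × 60 trials (≈ 40 screening trials), and the
calibration/power studies use 3 × 240 trials (8 blocks per session —
enough for stable Welch tests while keeping 100–200 replicates within
minutes on one CPU). The full 3 × 300 protocol remains the generator
default and is what the single-run acceptance quantities use.

* Band recovery: planted 9–12 Hz at depth 0.5; hit = selected window
  within ±1 Hz; expected ≥ 95/100 seeds.
* Null calibration: flat profiles; rejection count of the session 1 vs 3
  mean-degree Welch test at α = 0.05 must fall in the exact binomial
  95% interval over 200 replicates.
* Trend power: feedback profile must show a significant (p < 0.01)
  session-3 degree decrease and a positive MuSC slope in ≥ 90/100
  seeds; the flat profile must stay non-significant in ≥ 90/100.

## Known limitations

* Epoch-wise (not continuous) filtering and the 0.53-Hz band edge on
  2-s epochs make the lowest screening band (0.53–4 Hz) the least
  faithful of the grid.
* The EDF writer is minimal (16-bit, 1-s records, zero-padded tail,
  fixed header date) — sufficient for round-tripping simulated sessions,
  not a general-purpose exporter.
* Sampling rate, reference scheme and per-day trial counts of any real
  recording are taken from its metadata, never inferred.
* The pooled MuSC block series labels its task column "all"; per-side
  series can be built by selecting tasks before calling `musc_series`.
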
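# Methods

This note documents the models behind each pipeline stage, the tunable
parameters and their defaults, what the synthetic generators do and do not
emulate, and the numerical choices made where the underlying measurement
conventions are qualitative.

## Capacitance kinetics

**Model.** A depolarizing step (single 20 ms pulse, a 10×20 ms train at
10 Hz, or a 1 s pulse; −80 → +10 mV) evokes an instantaneous capacitance
jump at stimulus end, followed by recovery as membrane is retrieved.
Recovery is mono-exponential, bi-exponential (fast + slow components), flat
(no endocytosis), or an overshoot (recovery past baseline). The first
0.25 s after the stimulus is an artifact window: samples are carried in the
data with a boolean mask and excluded by every estimator, so the exclusion
rule is owned by the analysis, not the simulation.

**ΔCm_peak.** Baseline is the mean of the last 1 s before stimulus onset
(`baseline_s`, default 1 s). The post-stimulus plateau is estimated by
fitting a line to the first 2×`peak_window_s` (default 2×0.25 s = 0.5 s) of
unmasked samples and extrapolating to the stimulus end. A plain window mean
underestimates the jump by 1 − e^(−t_mid/τ) (≈4% at τ ≈ 10 s) because
endocytosis proceeds inside the window; linear extrapolation removes the
first-order bias (residual curvature bias −0.1% at τ = 10.2 s, −0.4% at
τ = 5 s) and the doubled fit window halves the leverage-amplified noise of
the extrapolated intercept (per-trace se ≈ 0.5× the sample noise SD).
`extrapolate=False` restores the plain mean of the first `peak_window_s`.

**Exponential fits.** `scipy.optimize.curve_fit` with bounds
τ ∈ (0.01, 10×window]. Time runs from the stimulus end, so fitted
amplitudes are referenced there and equal the generated jump on clean
traces. The bi-fit is initialized by a log-linear fit on the tail (slow
component) and peeling the early residual (fast component); τ₁ < τ₂ is
enforced by sorting, weight₁ = A₁/(A₁+A₂). Non-convergence is reported as
`model="unfit"`; a fit whose τ uncertainty spans the window (pure noise) is
flagged `well_determined=False`. With `model="auto"`, the bi-exponential is
kept only when it improves AICc by more than 10.

**Rate_decay.** Minus the least-squares slope of Cm over a window measured
from stimulus end: 0.5–4 s for the single 20 ms pulse (slow endocytosis),
0.5–1.5 s for the train (rapid component dominates there). The 1 s pulse
has no established window and defaults to 0.5–4 s; all windows are
overridable. A two-endpoint difference would be noisier; the slope
convention is kept and cross-checked in tests against an independent
normal-equation regression. Rate_decay_n = Rate_decay/ΔCm_peak; for mono
decays the companion quantity 1 − e^(−1/τ) (fraction retrieved in the first
second) is also reported.

**Mode classification.** Precedence: overshoot if the total decay exceeds
130% of ΔCm_peak; no-endo if below 30%; otherwise by the dominant time
constant (the component carrying the larger amplitude share): ultrafast
< 0.6 s, fast 0.6–6 s inclusive, slow > 6 s. Total decay is evaluated at
min(record end, 60 s post-stimulus) from the mean of the final 0.5 s —
whether the percentage classes are measured at a fixed time or record end
is not standardized, and this choice is tested at its boundaries (a decay
of exactly 30% or 130% falls through to the τ branch). `unclassified` is
returned only when no τ is available.

**ICa.** Peak inward-current magnitude during the stimulus, binned into
160–360, 400–900, 1000–1800 pA; values in the gaps are `out_of_bin`.

## SypH analysis

Each bouton trace is scaled so its pre-stimulus mean is 100%; the
experiment trace is the unweighted bouton mean per frame. ΔF/F is the
maximum of the experiment trace, searched from stimulus onset to 5 s past
the stimulus end (SypH can peak after the train), minus 100. The
normalized decay rate is minus the least-squares slope over
[t_peak, t_peak + window], divided by ΔF/F, in %/s; the window length is
configurable within the 4–10 s convention (default 6 s). The decay is
measured from the trace peak rather than the stimulus end for the same
reason the peak search extends past the train. A mono-exponential fit of
the post-peak decay is exposed as an alternative rate estimator
(`fit_syph_decay_tau`) but the slope is the reported statistic.

## Fusion-spot classification

**Detection physics.** F_655 (bath dye, strongly excited) exchanges freely
with the bath while the fusion pore is open, so it only bleaches once the
pore closes; F_PH (membrane label, weakly excited) persists until the
closed vesicle pinches off and diffuses away. Fusion onset is a
simultaneous step of F_PH and F_655 with concurrent onset of exponential
F_FFN decay (content release).

**Onset.** First frame where F_PH and F_655 both exceed baseline mean +
`k_sigma`·SD (k=4) within the same 3-frame window, with F_FFN beginning a
sustained decline within ±2 frames — tested as a drop of the 10-frame mean
after the candidate versus before it, against 2.5× the noise-scaled
standard error (floored at 2% of the FFN baseline so noiseless traces have
a usable threshold). Requiring all three channels rejects single-channel
artifacts; traces without an FFN channel never yield an onset.

**Classification** (thresholds are parameters; the underlying criteria are
qualitative): θ_dim = 0.5 (dimmed = below half the post-onset peak),
φ_sustain = 0.7, min_delay = 3 frames, ρ_parallel = 0.9. Channels are
smoothed (5-frame moving average) before thresholding. Decision order:

1. **shrink-fusion** — both channels end below φ_sustain of their peaks,
   the decline is parallel (Pearson r ≥ ρ over the decline epoch: from the
   post-onset peak until both channels reach 10% above their floors), the
   spot size (when present) drops by >20%, and the closure signature
   (below) is absent. The absence test matters: both channels of a closing
   vesicle also decline eventually, and over a long record their lagged
   decays still correlate, so parallelism alone cannot separate the two.
   The correlation uses heavier smoothing (2×5+1 frames) because the epoch
   is short and raw-noise variance would otherwise dominate the r estimate.
2. **close-fusion** — F_655 crosses θ_dim·peak while F_PH is still ≥
   φ_sustain·its peak, or the F_PH decline onset lags the F_655 one by ≥
   min_delay frames. Closure time is the onset-to-F_655-half-dimming
   interval (linearly interpolated) and must lie in 0.05–30 s; on synthetic
   traces it exceeds the true closure by the bleach offset
   τ_b·ln((P−F)/(P/2−F)), which the tests account for in closed form.
3. **stay-fusion** — both channels end ≥ φ_sustain of their peaks;
   `censored=True` when the record ends within 30 s of onset, since a
   later closure could have been missed.
4. **ambiguous** — a value, not an error.

Pre-spots (no FFN channel) are tested for **pre-close** with the same
dim-while-sustained rule against their initial levels; a parallel loss of
both channels is not pre-close.

**T_FFN.** Span = pre-onset plateau − post-decay floor (mean of the last 5
frames); T_FFN is the time between the interpolated crossings of 80% and
20% remaining signal (τ·ln 4 for exponential release). The value is
censored when there is no resolvable span or the tail is still losing >2%
of the span per second, which makes the floor estimate unreliable.

**Per-cell summary.** Prob_close-fusion = n_close/n_fusion (ambiguous
events stay in the denominator), Prob_pre-close = n_closed/n_pre-spots
(NaN when no pre-spots), mean T_FFN over non-censored events. Cells with
fewer than 5 fusion events are flagged `excluded` and omitted from group
aggregates but retained in the output. Only the first event per spot is
analyzed; sequential re-fusions at one spot are out of scope.

## EM morphometry

A vesicle row needs a diameter (nm) and/or a cross-section area (μm²).
Bulk endosome: diameter ≥ 80 nm, or area above that of an 80 nm vesicle
(π·(40 nm)² ≈ 0.005 μm²); either criterion suffices. The diameter
boundary is inclusive, and an area exactly equal to the threshold — the
area *of* an 80 nm vesicle — also counts, so the two criteria agree at the
boundary. HRP(+) vesicle density excludes bulk endosomes by default (the
two quantities are reported separately; configurable), and the bulk-area
density sums HRP(+) bulk endosome areas only, per μm² of profile area.
Group aggregates are means over profiles by condition × timepoint.

## Group statistics

Mean ± s.e.m. (sd with n−1 over √n; a single value reports NaN with a
flag, never a silent 0). Unpaired two-tailed Student's t-test with pooled
variance — the equal-variance test is the stated convention; Welch's
correction is available behind `equal_var=False`. Stars: p<0.05 \*,
p<0.01 \*\*, p<0.001 \*\*\* (strict inequalities). No multiple-testing
correction is applied, matching the reporting convention the pipeline
reproduces. The unit of analysis (cells, experiments, profiles) is the
caller's explicit choice, never inferred.

## Synthetic data: what is and is not emulated

All generators draw from a `numpy.random.Generator`; a fixed seed gives
byte-identical outputs, and noiseless traces satisfy their closed forms at
every sample.

- **Capacitance** (100 Hz, 60 s post-stimulus by default — ≥5τ coverage
  for τ up to ~12 s; the sampling cadence of the underlying lock-in
  recordings is not standardized, so a round value was chosen): baseline,
  instantaneous jump at stimulus end (intra-train exocytosis kinetics are
  not modeled because only the post-stimulus decay is analyzed), recovery
  per decay model, additive Gaussian noise, square-pulse ICa. Overshoot is
  modeled as mono-exponential recovery to a plateau below baseline with
  total decay = overshoot_fraction × jump. Not emulated: rundown, seal
  drift, lock-in admittance artifacts beyond the masked window.
- **SypH** (10 Hz; 10 s baseline, 10 s train, 60 s decay): linear rise to
  the bouton peak during the train; decay either mono-exponential or
  constant-rate (losing r% of the bouton's ΔF per second, the structure a
  slope statistic assumes), floored at baseline. Boutons are heterogeneous
  — per-bouton peaks and rates have CV 0.2 around the experiment means,
  reflecting the large bouton-to-bouton variability of real recordings —
  and are emitted on random raw-intensity scales so the normalization path
  is exercised. Not emulated: photobleaching, surface fraction, focus
  drift.
- **Fusion spots** (40–80 ms frames, default 60 ms; 40 s records): channel
  kinematics per mode as in the classifier section; spot size is a
  Gaussian-FWHM-like scalar that decays exponentially to 0 for shrink
  events. F_655 bleaching activates only when the pore is closed. FFN
  release is a single exponential from onset. Not emulated: diffraction,
  focal-plane loss, multiple events per spot.
- **EM tables**: profile areas ~ gamma (mean 0.35 μm²); vesicle counts ~
  Poisson(rate × area) for HRP(+), HRP(−) and bulk classes; regular
  diameters ~ normal (40 ± 5 nm, truncated below the bulk threshold so
  truth labels stay clean); bulk diameters ~ lognormal ≥ 80 nm. Rates are
  invented plumbing for recovery tests, not measured biology.

Passing recovery tests therefore shows the estimators are correct under
the assumed signal + Gaussian-noise structure; they do not certify
robustness to systematic artifacts (bleaching, drift, rundown) that real
recordings add.

## Validation cohorts and problem sizes

The acceptance script simulates 11 single-pulse traces (jump 531 fF,
τ 10.2 s, noise 10 fF), 11 train traces (jump 1565 fF, τ₁ 1.6 s at weight
0.31, τ₂ 15.5 s, noise 15 fF) and 20 SypH experiments (ΔF/F 161%, rate
3.9 %/s, 20 boutons, noise 3%), matching the control cohort sizes of the
recordings these conditions represent. Recovery tests compare cohort means
to the generating values at 2 s.e.m. of generator sampling; the sampling
s.e.m. is estimated from an independent 50-trace reference cohort because
an 11-sample sd estimate of its own spread is too noisy to set a 2σ
tolerance. The property suite uses 200 traces per fusion mode at 10%
channel noise and 10,000 null replicates for t-test calibration.

## Pipeline

One global seed fans out to per-modality seeds via
`numpy.random.SeedSequence.spawn` in fixed order (cm, syph, fusion, em),
so modalities can be re-run independently and identical config + seed
reproduce identical files (floats are written with a fixed format). Every
run writes its fully resolved config beside the outputs; a stage failure
raises a stage-named error and preserves earlier outputs. The demo config
pairs a control condition with an endocytosis-blocked one so the report
stage has real comparisons to make.

## Known limitations

- The capacitance fitter assumes the decay begins at stimulus end; delayed
  endocytosis onset would bias τ upward.
- Closure times carry the bleach-dependent half-dimming offset; absolute
  closure kinetics should be compared only within a constant-excitation
  dataset.
- The SypH rate is a window slope: for strongly curved (fast-τ) decays it
  underestimates the instantaneous initial rate; the mono-fit alternative
  is exposed for that case.
- Event detection needs ≥1 s of clean pre-event baseline and one event per
  spot/trace.
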
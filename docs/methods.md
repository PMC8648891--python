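# Methods

This note documents the models, parameter choices and numerical
conventions behind `betaburst`, and what the synthetic validation does
and does not establish about real data.

## Burst detection

The detector operates on the power spectrogram of a single continuous
time course (for EEG-fMRI work, typically an ICA component time course
representing sensorimotor beta activity; the package is agnostic about
how the channel is derived).

* **Time–frequency decomposition.** 5-cycle Morlet wavelets at 1-Hz
  steps from 1 to 40 Hz (`tfr.morlet_tfr`, backed by MNE's
  `tfr_array_morlet`). Wavelets are L2-normalised (unit energy); the
  downstream threshold is a per-frequency power ratio, so detection
  does not depend on this normalisation, only the reported `peak_power`
  scale does. The spectrogram keeps the signal's time resolution — no
  decimation — because the smoothing SD below is only 6 ms.
* **Smoothing.** 2-D Gaussian filter, SDs 1 Hz (frequency) × 6 ms
  (time), expressed in bin units as `sd_f / Δf` and `sd_t · f_s`;
  kernel truncated at ±4 SD, unit sum, reflect padding at the borders.
* **Peak picking.** Grey dilation with a 5×5 structuring element of
  ones with a zero centre; a cell is a candidate iff it strictly
  exceeds its dilation. The strict inequality means exactly tied
  plateaus yield no peaks — the natural tie rule for this construction.
  Border cells may be peaks (out-of-bounds neighbours are ignored),
  but events within half a wavelet support of a recording edge are
  discarded per frequency, because the transform is unreliable there.
* **Thresholding.** Keep a candidate iff its (smoothed) power is at
  least `threshold_factor` (default 6) times the median over all time
  points of its frequency row, medians computed on the smoothed
  spectrogram (a flag switches to raw-power medians). Peaks are then
  restricted to the configured beta band, 13–30 Hz by default. No
  merging of nearby peaks is performed (an optional `min_separation`
  exists, default 0).

### The noise floor is part of the method

Gaussian 1/f background alone produces strict local maxima exceeding
6× the row median at ≈0.4–0.7 events/s across the beta band — a
property of chi-square power fluctuations, independent of the noise
amplitude (the threshold is scale-free). On real recordings such events
are indistinguishable from "true" bursts; on synthetic data they bound
the achievable precision whenever injected bursts are sparse. This is
why the detector-validity study (below) uses a burst-dominated signal,
and why absolute burst rates from different preprocessing pipelines
should not be compared without matching the background statistics.

## Burst statistics

* Condition rates: count in the union of a condition's intervals ÷
  total duration; intervals and all windows are half-open `[lo, hi)` so
  boundary events are counted once.
* Event-locked curves: 500-ms windows centred on each lag, stepped
  every 50 ms by default; rate = pooled count ÷ (n_events · window).
* PMBR: post window +0.5…+1.0 s, baseline −3.0…−1.5 s relative to each
  button press; pooled across responses (per-response averaging is
  available and identical for equal windows). Responses whose windows
  extend past the recording are dropped entirely. PMBR equals the
  event-locked curve averaged over the same windows at matched
  window/step — asserted in the tests.
* Mann–Whitney U uses the exact distribution for pooled n ≤ 20 without
  ties, otherwise the normal approximation with tie correction;
  r = |Z|/√N. Welch's t is reported with pooled-SD Cohen's d.
* The one-way repeated-measures ANOVA computes the classical
  SS decomposition; the Greenhouse–Geisser ε comes from the
  double-centred condition covariance, ε = (Σλ)²/((k−1)Σλ²), clipped to
  [1/(k−1), 1], and is applied unconditionally (no Mauchly gating; with
  k = 2, ε = 1 analytically). Partial η² = SS_cond/(SS_cond+SS_err).
* Spearman associations use ties-corrected ranks; covariate adjustment
  residualises *both* variables on the covariates (plus intercept) by
  least squares before rank correlation. This is one of several
  conventions for a "partial Spearman"; it is the documented one here.

## BOLD model

* Canonical double-gamma HRF: gamma-density difference with response
  delay 6 s, undershoot delay 16 s, unit dispersions, peak:undershoot
  6:1, sampled on [0, 32] s and peak-normalised.
* Designs are built on a microtime grid of TR/16 so impulse events
  between scan times are not lost; boxcars are additive (columns are
  linear in events), impulses are unit height; columns are sampled at
  scan acquisition times i·TR. An intercept is always appended; an
  optional cosine high-pass basis (cutoff 128 s) is off by default.
* Fitting is plain voxelwise OLS — no prewhitening and no temporal
  derivatives. This is a deliberate simplification of the full SPM
  pipeline: validation here is recovery on synthetic data generated by
  the same forward model, for which OLS is unbiased and exactly
  calibrated. Rank-deficient designs fall back to the pseudo-inverse
  with a warning. Contrast t-tests use df = scans − rank(X).
* FDR is Benjamini–Hochberg; clusters use 26-connectivity by default
  (6/18 configurable); spherical ROIs (default radius 10 mm) include a
  voxel iff its centre, mapped through the NIfTI affine, lies within
  the radius.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes.

* **Task schedule.** Per run: a 30-s lead-in rest, then seven blocks
  each followed by a 30-s rest; a block is three 30-s sub-blocks
  (0/1/2-back in random order) separated by 10-s rests; 15 letters per
  sub-block at 2-s onsets, exactly 4 targets (0-back target: the letter
  'X', letter id 0 of 10; 1/2-back: match at lag 1/2). Non-target
  positions are filled so that a brute-force scan of the match rules
  recovers exactly the intended targets.
* **Behaviour.** Each target is hit with probability `hit_rate`
  (default 0.95, optionally per condition); reaction times are shifted
  lognormal, `0.3 + 0.15·lognormal(0, 0.5)` s by default (median
  ≈ 450 ms). There are no commission errors.
* **Burst point process.** Thinned inhomogeneous Poisson process with
  intensity tonic(condition) × suppression(t) + boost(t): tonic rates
  default to rest 0.40, 0-back 0.32, 1-back 0.26, 2-back 0.20 bursts/s
  (a monotone load-dependent decrease of plausible magnitude; the
  underlying study reports the ordering, not numeric rates); rate is
  halved (`poststim_suppression = 0.5`) for 0.5 s after every stimulus
  and boosted by `pmbr_boost` (default 0.3 bursts/s) × a group
  `attenuation` scalar in the 0.5–1.0 s window after every response.
  Ground truth stores every injected burst and the model-implied
  expected rate per condition (time-average of the intensity on a 5-ms
  grid).
* **Waveform.** Hann-enveloped cosines with centre frequency uniform on
  15–25 Hz and duration uniform on [0.10, 0.15) s, riding on 1/f^α
  Gaussian noise (α = 1, unit SD) at 250 Hz. The 100-ms lower duration
  bound (rather than, say, 50 ms) is deliberate: a transient of barely
  one beta cycle has a spectral width of well over 10 Hz, so its
  "centre frequency" is undefined at the ±2 Hz resolution the
  validation uses for event matching — we measured +3 to +6 Hz peak
  biases for 50–70 ms bursts under every wavelet normalisation. At
  2–3.75 cycles the assigned frequencies are physically meaningful
  while respecting the < 150 ms burst-duration regime.
* **BOLD.** Voxel series are `design · β + N(0, σ²)` with the design
  built by the analysis itself, so coefficient recovery is an exact
  self-consistency check.

### What the synthetic data does not model

MR gradient/cardioballistic artefacts, volume conduction and channel
mixing, non-Gaussian or non-stationary background, burst waveform
variability beyond duration/frequency/phase, serially correlated BOLD
noise, and head motion. Passing validation therefore certifies the
*pipeline arithmetic* (detection geometry, window bookkeeping, model
calibration), not performance on any particular real recording.

## Validation studies (`betaburst.validation`)

Problem sizes were fixed a priori from power calculations:

* **Detector validity** — 600 s at 250 Hz with one burst every 0.4 s
  (±50 ms jitter) cycling through 15/18/21/24 Hz at amplitude 8
  (matched events sit at median ratios ≥ 10). The dense, burst-dominated
  train inflates the row medians, keeping the noise floor below
  threshold; recall and precision against ground truth (±25 ms, ±2 Hz,
  greedy one-to-one matching) are ≈ 0.98, and the event list is
  bit-identical under signal scaling by 0.1× or 10×. At sparse,
  task-like burst rates the noise floor bounds precision near
  rate/(rate+0.4/s) — see "noise floor" above.
* **Rebound recovery** — 5000 responses 10 s apart on a rest-only
  background; the PMBR statistic recovers boosts of 0, 0.3 and
  0.6 bursts/s within Poisson counting error. (On the full task
  schedule the statistic acquires a small positive bias ≈ +0.17 ×
  tonic × (1 − suppression), because stimulus-suppression windows
  overlap the −3…−1.5 s baseline — a property of the task design, not
  of the estimator.)
* **Group study** — 200 replicates of 30 "controls" (attenuation 1.0)
  vs 48 "patients" (attenuation 0.5), one task run per subject;
  Mann–Whitney on per-subject PMBR detects the difference in ≈100% of
  replicates. Load ordering rest > 0 > 1 > 2-back is checked on six-run
  recordings (≈1260 s per n-back condition; adjacent realized rate
  differences ≈ 0.05 bursts/s give pairwise z ≈ 2.6, hence ≈98% joint
  ordering probability).
* **GLM calibration** — noiseless refits recover coefficients to
  < 1e-8; null burst-contrast p-values pass a KS uniformity test;
  nominal 95% CIs cover the injected effect within binomial error; and
  replacing true bursts with random surrogate events in models of
  burst-driven BOLD yields an FDR rejection rate well below q = 0.05
  (the "fake events" control).

## Known limitations

* The detector reports point events only; burst duration and shape are
  not estimated.
* Whether the row median should be computed on smoothed or raw power
  is ambiguous in the field; smoothed is the default and a flag
  switches it.
* EDF export is not provided (signals are written as CSV + JSON
  sidecar with the sampling rate); EDF input is read via MNE.
* OLS without prewhitening understates BOLD autocorrelation on real
  scanner data; t-statistics on real data should be interpreted with
  that in mind or refit with a dedicated fMRI package.
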
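# betaburst

Beta-band activity in sensorimotor cortex is not a sustained oscillation
but a train of brief, high-power transients — *beta bursts* of less than
150 ms. `betaburst` implements a single-trial burst analysis for
continuous electrophysiological recordings acquired during an n-back
working-memory task (optionally with concurrent fMRI): it detects bursts
as suprathreshold local maxima of a smoothed time–frequency spectrogram,
quantifies the post-movement beta rebound (PMBR) and load-dependent
burst rates, and estimates burst-locked BOLD correlates with an
impulse-regressor general linear model. A synthetic-data generator with
ground-truth burst labels makes every stage testable end to end.

It is aimed at EEG/MEG researchers studying transient beta dynamics and
at EEG-informed fMRI analyses that need point-event regressors.

## Method

**Detection.** For a continuous neural time course x(t) sampled at f_s,
power P(f, t) = |W_f x(t)|² is computed with 5-cycle Morlet wavelets at
1-Hz intervals from 1 to 40 Hz. P is filtered with a two-dimensional
Gaussian (SD 1 Hz × 6 ms). Candidate peaks are the cells strictly
exceeding the grey dilation of P under a 5 × 5 structuring element of
ones with a zero centre (i.e. strict local maxima). A peak at frequency
f is kept iff

&nbsp;&nbsp;&nbsp;&nbsp;P(f, t) ≥ 6 · median_t P(f, t),

the median taken over all time points at that frequency. Retained peak
times inside the beta band (default 13–30 Hz) are the burst events.
Because both rules compare power to power, detection is invariant to the
overall signal scale.

**Burst statistics.** Condition-wise rates are event counts divided by
the total duration of each condition's intervals. Event-locked rate
curves use 500-ms sliding windows. The rebound statistic is

&nbsp;&nbsp;&nbsp;&nbsp;PMBR = rate(+0.5 … +1.0 s after button press) − rate(−3.0 … −1.5 s before),

with half-open windows pooled across responses. Group comparisons use
Mann–Whitney U (effect size r = |Z|/√N) or Welch's t (Cohen's d);
repeated-measures ANOVA applies the Greenhouse–Geisser correction;
associations use Spearman's ρ with optional covariate residualisation.

**BOLD model.** First-level design matrices contain the 0/1/2-back
sub-blocks as boxcars and motor responses and beta bursts as impulses,
all convolved with the canonical double-gamma HRF on a microtime grid
(TR/16); voxelwise OLS yields contrast t/p maps, post-processed with
Benjamini–Hochberg FDR, a minimum cluster extent (default k ≥ 20), and
1-cm spherical ROI summaries.

**Generator.** The bundled simulator reproduces the task structure
(seven blocks per run of 0/1/2-back sub-blocks, 15 letters each with 4
targets at 2-s spacing, 30-s/10-s rests), Hann-enveloped beta bursts on
1/f noise driven by an inhomogeneous Poisson process with tonic
load-dependent rates, post-stimulus suppression and a post-response
rebound boost, behavioural responses, and BOLD series generated from the
same design the analysis fits.

## Worked example

Run the whole pipeline on one synthetic run (≈17 min of task at 250 Hz):

```bash
betaburst demo --runs 1 --seed 0 --out demo_out
```

prints

```json
{
 "baseline_rate": 0.675,
 "glm_mean_burst_beta": 0.49497872614030725,
 "n_bursts": 769,
 "n_responses": 80,
 "pmbr": 0.3999999999999999,
 "post_rate": 1.075,
 "rate_0back": 0.7095238095238096,
 "rate_1back": 0.6619047619047619,
 "rate_2back": 0.7047619047619048,
 "rate_rest": 0.8763157894736842
}
```

769 bursts were detected in 1010 s. The detected rates combine the
injected bursts (0.2–0.4/s depending on condition) with the noise-floor
events that the 6×-median rule inevitably admits in 1/f background
(≈0.4/s — see `docs/methods.md`); rest shows the highest rate and the
n-back conditions lower ones. The burst rate in the half-second after
each of the 80 button presses exceeds the pre-response baseline by
0.40 bursts/s — the post-movement beta rebound (generated boost:
0.3 bursts/s plus task-baseline bias). Refitting the generated BOLD
recovers the burst regression coefficient (true value 0.5) at 0.495.
`demo_out/` also contains the signal, events table, burst table, ground
truth and per-voxel GLM results; `betaburst simulate/detect/rates/pmbr/
compare/glm` expose the individual stages.

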
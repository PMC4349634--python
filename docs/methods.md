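# Methods

`spikesta` re-implements, as a tested pipeline, the analysis chain used to
estimate the epidural-EEG correlate of a single cortical action potential from
simultaneous micro-electrode and epidural-EEG recordings, together with the
closed-form forward models that interpret that estimate.  Because such
recordings are not publicly deposited, the pipeline is driven by a synthetic
session generator that reproduces the statistical structure the analysis
assumes; every empirical statement below is computed by the test suite or by
`scripts/acceptance.py`.

## Signal model and estimators

**Spike-triggered average (STA).**  Epidural EEG trials (nominally 6 kHz,
hardware band 3–3000 Hz, voltages in nV) are band-pass filtered per trial with
a zero-phase Fourier-domain filter whose ideal band mask is convolved with a
Gaussian of 117 Hz half-width at half-maximum (the mask is exactly 0.5 at each
cutoff; no ringing).  Two presets are used throughout: wideband 3–3000 Hz with
±15 ms windows and 30 ms minimum spike separation, and high-frequency
800–3000 Hz with ±3 ms windows and 6 ms separation.  Filtered trials are
upsampled to 10 kHz by linear interpolation; segments centred on each retained
spike's first negative peak (inclusive lag grid, 61 samples for ±3 ms) are
averaged.  Spikes closer than the minimum separation are removed *pairwise* —
both members of a close pair are dropped, since a neighbour on either side
contaminates the segment.

**Shift predictor and baseline correction.**  Evoked responses introduce
stimulus-locked potentials that survive averaging even without any spike/EEG
coupling.  The null is estimated by reassigning every spike to a uniformly
drawn *different* trial while keeping its post-stimulus latency (no
derangement constraint beyond "different from own trial"); the mean STA over
100 such shuffles is subtracted from the STA.  By construction this correction
is not applied to the late-window (200–290 ms) STA or to wideband STA spectra;
the pipeline enforces this by contract and records a `baseline_corrected`
flag.  Confidence bands are ±2.58 SEM across spike-triggered segments (99%
limits), with the SEM referred to the unshuffled segment count.

**Peak significance.**  The maximal absolute STA amplitude within
[−0.3, 0.5] ms is compared against the distribution of the same statistic over
bootstrap STAs assembled from shuffled-trigger segments (resampled with
repetition, segment count conserved); p is the fraction of bootstrap peaks
exceeding the observed peak, with no multiple-comparison correction.  We
considered the fully pairwise variant (both peak distributions resampled and
compared replicate-by-replicate) and found it essentially never rejects under
the null — the folded max statistic makes that comparison extremely
conservative — so the observed-versus-bootstrap-null form is the default and
the pairwise form is available as `resample_observed=True`.  The implemented
default holds its nominal level (verified at 0.05 over 200 null sessions).
The [−0.3, 0.5] ms window at 10 kHz spans 9 inclusive samples; we use the
inclusive grid.

**Log-spaced spectra.**  STA spectra are estimated on a grid of frequencies
equidistant on a log scale (8 per octave; consecutive ratio 2^(1/8)).  Such a
grid cannot contain 0, so it starts at f_min = 2/duration.  Per frequency the
waveform is truncated to an integer number of periods, Hann-windowed, and
projected onto a sine/cosine pair; power is the squared amplitude of the
projection (2|c|/Σw)², making a unit sine grid-exact.  The spectrum is then
smoothed by a half-octave moving average over the grid ([f·2^(−1/4),
f·2^(1/4)]); smoothing is applied to linear power.  Frequency-wise
significance uses 500 bootstrap spectra of shuffled-trigger STAs and two-tailed
tail fractions (with add-one continuity so p > 0).

**Multitaper PSD.**  Slepian tapers with the stated 600 Hz read as the full
concentration bandwidth (half-bandwidth W = 300 Hz, configurable), NW =
duration·W, taper count floor(2 NW) − 1, one-sided density normalised so
∑PSD·Δf equals the variance.  Note a consequence used in the tests: a pure
spectral line is estimated as a plateau of width ≈ 2W, so peak locations are
meaningful only to ±W.

**Correlated-population model.**  Pairwise synchrony is modelled as a Gaussian
cross-correlogram excess f_xcf(t) = a_xcf·exp(−t²/b_xcf) (peak A_xcf = a_xcf
in coincidences/s per trigger spike, half-amplitude width T_xcf =
2√(b_xcf ln 2)); the single-spike correlate as a Mexican hat g_STA with peak
A_STA = 2a_STA/b_STA and side-lobe separation T_STA = √(6 b_STA).  The
expected contribution of N correlated neurons is N·(f_xcf ∗ g_STA) — again a
Mexican hat with b = b_xcf + b_STA and amplitude 2√π·N·a_xcf·a_STA·
√(b_xcf·b_STA)/(b_xcf+b_STA)^{3/2}.  All internal times are ms and rates are
converted from 1/s at the boundary; with A_xcf = 0.008/s, T_xcf = 17 ms,
A_STA = 60 nV, T_STA = 0.45 ms and N = 10⁷ this gives A_cSTA ≈ 0.506 nV and
T_cSTA ≈ 25.01 ms, and the closed form matches direct numerical convolution to
better than 10⁻⁶ relative error over a 10×10 parameter sweep.

**Burst prediction.**  Per-cell PSTHs (0.1 ms bins, expected spikes per trial
per bin) are convolved with the per-cell STA (nV per spike, lag 0 mapped onto
the spike bin, mode "same") and averaged across cells; keeping the PSTH in
spikes/bin/trial makes the recorded/predicted peak-to-peak ratio a
dimensionless neuron-count estimate.  The confidence band resamples cells with
repetition to the original count and, per drawn cell, resamples its segments
(count conserved) before convolving; the band is the pointwise 5th/95th
percentile over 500 replicates.  The recorded burst used for the ratio is
band-passed per trial and then averaged.

**Dipole forward model.**  V = boundary_factor·(η/4π)·Q·cosθ/r² with
r = √(h² + d²/4); computing in Ω·mm, nA·mm and mm yields nV with no extra
constants.  Defaults: η = 2.47 Ω·m, h = 2.18 mm, d = 10 mm, boundary factor 4
(resistivity boundary + bipolar montage, taken as given).  The published
"20–78 nV" range matches integer truncation of the computed 20.61/78.48 nV,
so the report emits both raw and truncated values; r is reported as computed
(5.455 mm) rather than the printed rounding (5.46 mm).  Scalp extrapolation
divides by a burst attenuation (default 10) times a neuron-count ratio
(default 10); the noise-over-band helper emits the exact 10 nV/√Hz × √(1 kHz)
= 316 nV rather than the conventional "≈300 nV" rounding.

## Synthetic sessions

The generator emulates a median-nerve stimulation session: 1031 trials of
333 ms (3 Hz repetition) by default, EEG at 6 kHz and a micro-electrode
channel at 24 kHz.  Components:

* **Noise.**  White noise band-passed to 3–3000 Hz and rescaled so the
  800–3000 Hz band has SD 700 nV (the study's high-frequency noise floor).
  The generator deliberately has no 1/f structure — the on-going low-frequency
  spectrum of real epidural EEG is not reproduced — and flags this with
  `SessionConfig.flat_noise_spectrum`.  Consequently, passing tests constrain
  the high-frequency analyses; wideband results on real data would face
  additional low-frequency interference.
* **Evoked response.**  A biphasic slow SEP (default 20 µV, peaking at 10 ms)
  plus a Hann-windowed 600 Hz burst at 8–18 ms (default 2 µV) added
  identically to every trial — orders of magnitude above the per-spike kernel,
  which is what makes the shift-predictor correction necessary.
* **Spikes.**  Inhomogeneous Poisson trains (thinning) with a 1 ms absolute
  refractory period enforced by deleting the later spike.  The default rate
  profile has an 8 spikes/s stationary floor (matching the late-window rate
  implied by the study's spike counts), a broad driven component over
  5–50 ms, and sharp rate bumps repeating at 1/600 s within 6–20 ms.  One cell
  per session by default; multi-cell sessions via lists of kernels/profiles.
* **Per-spike kernel.**  A Mexican hat (default A = 60 nV, T = 0.45 ms,
  latency 0.05 ms) evaluated in closed form at the EEG sample times for each
  spike.  Array-valued kernels are inserted with fractional-delay linear
  interpolation; for closed-form kernels direct evaluation is exact and is
  what interpolation approximates.
* **Correlated pairs.**  Jittered shared events: a mother Poisson process of
  rate a_xcf·r·2√π·σ (σ = √b_xcf/2) copied into both trains with independent
  Gaussian jitter, yielding a correlogram excess of peak a_xcf and
  half-amplitude width T_xcf.  At the published synchrony (0.008/s, 17 ms) the
  excess is a fraction ~10⁻⁴ of baseline, so desk-scale estimates are noisy;
  tests therefore validate the construction quantitatively at a stronger
  feasible correlation and check consistency (within the fit's own SE) at the
  published one.

**What recovery means.**  A 0.45 ms kernel is necessarily attenuated by the
acquisition chain — 6 kHz sampling, the 800–3000 Hz band, and alignment to the
nearest 10 kHz sample: the expected recoverable peak-to-peak of a nominal
400 nV kernel is ≈242 nV.  The STA is an unbiased estimator of the *aligned,
band-limited* kernel, which the generator computes independently of the STA
code path (`expected_sta_kernel`, a direct phase-average over the spike's
position relative to the sampling grid).  Parameter-recovery tests therefore
compare against that reference; comparing against the continuous amplitude
would mistake acquisition physics for estimator bias.

## Problem sizes and numerical choices

Validation experiments use sizes chosen to make their statistical tolerances
meaningful while staying desk-scale: kernel recovery uses 400 trials at
20 spikes/s (≥2000 retained segments per run, 100 seeded runs, coverage
≥99/100 at the 2.58-SEM band evaluated at the waveform extrema); null
calibration uses 200 kernel-free sessions (binomial 99% CI around 0.05);
the shuffled-STA scaling law uses segment counts 50–3200 with 40 repetitions
per count (slope −0.5 ± 0.1).  Bootstrap resampling is chunked to bound
memory.  Filtering uses the plain DFT with no padding (circular); STA windows
are extracted after whole-trial filtering, which keeps wrap-around away from
the analysed segments, and trials are filtered individually.  All randomness
descends from one seed through per-purpose `SeedSequence` children; identical
seeds give bit-identical sessions, shuffles, and bootstrap draws.

## Known limitations

* No 1/f background, no drifting electrodes, no waveform nonstationarity —
  the grouped spike/STA covariation analyses run on synthetic data but their
  cross-talk-detection purpose is only meaningful on real recordings.
* Spike sorting proper (cluster cutting on shape features) is out of scope;
  detection assumes a single dominant negative lobe per unit.
* The dipole model is a single homogeneous-medium dipole with a fixed boundary
  factor; no layered head model.
* The log-spectrum truncation makes the effective record length
  frequency-dependent; at the lowest grid frequencies (< 4 periods in the
  record) variance is visibly higher.
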
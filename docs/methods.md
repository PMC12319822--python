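# Methods

This note documents the models and numerical choices behind
`gammaflow`: what each analysis stage computes, what the synthetic-data
generator emulates (and deliberately does not), and where the design
was genuinely open.

## Analysis chain

### Conditioning

Continuous recordings are polyphase-resampled (anti-aliased,
`scipy.signal.resample_poly`; event indices rescaled with
round-half-away-from-zero) and filtered zero-phase
(forward–backward second-order sections, so event latencies are not
shifted).  The band-pass is a 4th-order Butterworth; each notch is a
3rd-order Chebyshev-II band-*stop* with 30 dB stop-band ripple.  The
Chebyshev stop is used because a low-order Butterworth band-stop only
attenuates well at its geometric centre: with the asymmetric 49–55 Hz
stop interval, a 50 Hz tone survives an order-2 Butterworth at 15%
amplitude even after forward–backward application, while the
Chebyshev-II design guarantees ≥ 30 dB (60 dB after filtfilt) across
the whole interval.

The default notch for synthetic data is 49–51 Hz: the generator's only
narrowband interference is the 50 Hz line sinusoid.  The
`experiment1` preset widens it to 49–55 Hz with additional notches at
99–101, 149–151 and 199–201 Hz, matching an acquisition setup whose
head-position-indicator coils leave artifacts just above the line
frequency.

### Bad-segment detection

The signal standard deviation is pooled across all non-EMG channels in
non-overlapping 1 s windows, and the window series is screened with
the generalised extreme studentised deviate (GESD) test at α = 0.05,
with at most 20% of windows removable.  GESD is Rosner's sequential
procedure: candidates are removed one at a time (largest studentised
deviation first, ties broken by lowest index), each step i yields a
statistic R_i and a critical value λ_i from the t distribution, and
the declared outliers are the first i* removals where i* is the
largest i with R_i > λ_i.  A zero-variance input yields no outliers.
Flagged windows are masked — dropped from the covariance estimate and
from epoch eligibility — not interpolated.  The EMG channel is exempt
from the metric: its bursts are signal.  The 20% cap is applied
globally (across the pooled-channel metric), not per channel.

### EMG movement marks

Per trial (segmented −1..+3 s around the Go stimulus): high-pass at
10 Hz → RMS envelope with an 80 ms window → threshold from the
−600..−200 ms pre-Go baseline → onset = start of the first
non-overlapping 24 ms window (scanning forward from Go) whose mean
envelope exceeds the threshold; offset = start of the first
supra-threshold 120 ms window scanning backward from the trial end.

Two choices here deserve explanation:

* **Envelope alignment.**  The RMS window is *trailing* (causal).  A
  centred window lets the envelope rise up to ~40 ms before the burst,
  which biases detected onsets early by up to ~45 ms at high burst
  amplitude; the causal form keeps the onset error within one 24 ms
  window.  The same envelope serves the backward offset scan, whose
  120 ms window grid absorbs the envelope's ~80 ms lag.
* **Threshold statistics.**  The batch detector (`mark_movements`)
  uses the baseline envelope mean + 3 × envelope SD with statistics
  *pooled across all trials*: a single 0.4 s baseline contains only
  ~5 independent envelope values, so per-trial envelope-SD thresholds
  are noisy enough to false-trigger on ~10% of clean trials.  The
  single-trial detector (`detect_onset_offset`), which cannot pool,
  anchors the threshold at the baseline envelope mean + 3 × the
  *raw-signal* SD instead — the raw SD is well determined from 0.4 s
  and pure noise stays far below threshold.  Both thresholds represent
  "3 standard deviations of the baseline EMG activity"; the two
  readings are isolated in the two functions.

Trials are then excluded when the envelope peak, reaction time or
movement time is a GESD outlier (α = 0.05) across trials; a trial
flagged on several metrics is excluded once with all reasons listed.

### Sensor normalisation and beamforming

Coil types with heterogeneous physical units (gradiometers,
magnetometers) are equalised by dividing each group's data by the
smallest eigenvalue of its channel covariance.  The forward model is
divided by the same factors (`scale_leadfield`) — without the matching
rescale the minimum-variance filter treats the true source's
normalised topography as interference and suppresses it.

The spatial filter is the scalar linearly constrained minimum-variance
(LCMV) beamformer: `w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹` with unit gain `w·l = 1` at
the target.  The data covariance is computed across the whole retained
(band-filtered) time course, separately per band, and inverted on its
top-50 principal subspace (clipped to the available rank, spectral
floor 10⁻¹² × the largest eigenvalue).  A source whose projected-power
denominator vanishes (relative to the best-resolved source) is flagged
unresolvable rather than silently inverted.  Variance maps for
localisation are unit-noise-gain normalised (divided by ‖w‖²), which
cancels the depth bias that otherwise concentrates projected noise at
weak-leadfield voxels; the band *features* need no such correction
because baseline division cancels the same factor.  The synthetic
sources have fixed orientation, so the scalar filter is exact; no
vector orientation estimation is performed.

### Time–frequency decomposition and band peaks

Per trial and location, power is estimated with DPSS multitapers:
1.6 s windows in 200 ms steps, zero-padded so the frequency grid falls
exactly on 1 Hz multiples.  The spectral half-bandwidth is 2.5 Hz
(time–half-bandwidth product 4, hence 7 tapers) — a conventional
smoothness for γ-band estimation; it is configurable.  Windows are
placed fully inside the epoch (no partial windows) and stamped at
their centres; with −2..+2 s epochs the centres run −1.2..+1.2 s and
include 0.  Note the 1 Hz spacing is a zero-padded *grid* spacing; the
true resolution is set by the 1.6 s window and the 2.5 Hz bandwidth.

Baseline correction divides by the across-trial mean baseline power
per frequency × location: `(P − B)/B`, so the trial-average over the
baseline window is exactly zero.  The baseline is −1..−0.5 s relative
to movement onset (−1.5..−1 s relative to movement *offset* for the
post-movement β rebound, whose epochs are re-locked to the offset).

Band features average corrected power over each trial's *own*
movement window (onset→offset; offset→offset+1 s for the β rebound),
then across trials, and reduce the remaining frequency × ROI-location
plane by max (ERS) or min (ERD).  Ties break toward the lowest
frequency, then the lowest location index.  The subject's feature is
the reduced value, its frequency, and its location; `power_map`
repeats the same averaging at a fixed frequency for every location.

### TMS / SICI

MEP trials pass four ordered rejection rules: (1) amplitude < 0.1 mV;
(2) pre-pulse EMG > 0.1 mV in the 80 ms before the pulse (maximum
absolute value; an RMS variant is available); (3) outside mean ± 2 SD
per condition × block, with the SD recomputed on rule-1/2 survivors
and including the candidate; (4) one two-sided Grubbs iteration
(α = 0.05) per condition — at most one further rejection each.  A
trial is tagged with the first rule that rejects it.  Note rule 4 can
only fire when block-wise and condition-wide spreads differ: within a
single block, any Grubbs-significant point already exceeds ±2 SD.
SICI is the ratio of mean conditioned to mean unconditioned MEP
amplitude over retained trials; early/late pre-movement protocols form
separate pairs, and the pooled pre-movement value is their mean.

### Learning scores

Sequence task: after dropping incorrect presses, anticipatory
responses (RT ≤ 0 re cue) and per-block ±2 SD outliers (single pass),
the score is 100 × (mean RT of blocks 10–14 − mean RT of block 2) /
(mean RT of block 2); negative = learning.  Visuomotor task: trials
are assigned to six bins of equal cumulative movement time — each
trial goes to the bin containing the midpoint of its own interval on
the cumulative clock (the midpoint rule resolves boundary-straddling
trials) — and the score is the bin-mean difference last − first for
movement time and for angular error.

### Correlation inference

Bivariate outliers are removed by bootstrapping the Mahalanobis
distance: 1000 resamples each yield a mean/covariance pair, every
point's squared distance is evaluated under each, and a point is
removed when its median bootstrap distance exceeds the 0.975 quantile
of χ²₂.  Both the resample count and the quantile are configurable.

The Bayes factor for the Pearson correlation integrates Hotelling's
exact sampling density of r given ρ over a stretched-beta prior on ρ
with width κ (κ = 1, the standard default, gives the uniform prior),
against the density at ρ = 0.  The integral uses 300-node
Gauss–Legendre quadrature of the exact integrand in log space; the
test suite checks it against adaptive quadrature to 10⁻⁶ relative
error and against an independent closed-form implementation.
Evidence categories: anecdotal 1–3, moderate 3–10, strong 10–30, very
strong 30–100, extreme > 100 for H1, with reciprocal bands for H0;
boundary values fall to the stronger side, BF₁₀ = 1 is "anecdotal
(none)".

Correlation comparisons Fisher-transform both coefficients.
Independent samples use the classical
`z = (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3))`.  Dependent comparisons sharing
one variable use Steiger's Z with the pooled-correlation covariance
term; the correlation between the two non-shared variables (`r23`)
defaults to 0 when unknown, which under-corrects (is conservative)
for positively related measures.  p-values are two-tailed normal.

## Synthetic-data generator

The generator emulates, per subject: a Go/NoGo session (70 trials,
exactly 20% NoGo, 1 s cue–stimulus gap, 200 ms stimuli, 2–4 s uniform
ITI), its Go-only variant (140 trials, ITI ∈ {2.7..4.7} s in 0.5 s
steps), a paced-press session (4 digits × 8 flashes at 1 Hz, 32-flash
cycles × 8), TMS trial tables (15 trials per pre-movement protocol,
13 per rest condition), a 15-block sequence-learning session (random
blocks of 30 cues; 3 repeats of a fixed 10-item sequence with 3:3:2:2
key counts), and a visuomotor session generated until ~19.7 min of
cumulative movement time.

### Sensor model

`data = gain × source activity + noise`.  Each band's source sits at
one voxel of a small regular grid and consists of (a) a narrowband
noise carrier at the subject's true peak frequency (4 Hz bandwidth)
modulated by a movement-locked envelope, plus (b) a broadband in-band
background at 0.25 × unit RMS.  The background stands in for ongoing
cortical broadband activity: without it the baseline spectrum at the
source is degenerate (the only baseline power near the peak is the
carrier's own), relative baseline correction then *suppresses* the
true peak relative to its flanks, and every recovered peak frequency
lands ~4 Hz off.  Envelope shapes are Hann-tapered boxcars / Hann
bumps: mid-γ spans onset→offset; slow-γ is a 0.8 s bump centred on
the offset; β keeps its carrier at unit amplitude through the
baseline, drops by 60% from just before onset to offset, and rebounds
(+80%) for ~1 s after offset.  Subjects' default peak frequencies are
β 19 Hz, slow-γ 43 Hz, mid-γ 71 Hz, at three adjacent central voxels.

The leadfield decays as 1/(d² + (h/2)²) from each source to sensors
on a jittered plane two grid-spacings above the volume; magnetometer
rows are scaled by 0.05 relative to gradiometers (folded into both
data and returned leadfield) so the coil-type normalisation is
genuinely exercised.

Noise is a white + 1/f mixture (unit RMS per channel) with a slow
±10% amplitude drift, plus a dominant < 8 Hz background at 2 × RMS
and a common 50 Hz sinusoid at 2 × RMS.  The low-frequency background
and the drift matter for realism of the *artifact detector*: in a
perfectly stationary broadband background, any movement-related power
change is an extreme outlier of the window-SD metric and GESD would
flag exactly the movement windows.

`snr` is the **array-level in-band SNR**: per band, the movement
-window signal RMS summed over the array divided by one channel's
noise RMS within that band's frequency range.  Under this convention
the beamformer's output SNR tracks the parameter directly, and the
per-channel footprint of a burst shrinks with √(channels), as for a
real array.  The EMG channel is separate: baseline unit-RMS noise
with multiplicative bursts at `emg_snr` (default 8) × baseline RMS
from true onset to offset, 20 ms ramps.

### Population layer

Latent trait pairs are bivariate standard normal with the configured
correlation, mapped to generator parameters by monotone affine maps
clamped to plausible ranges (slow-γ peak 35–57 Hz, SICI ratio
0.1–1.4, mid-γ amplitude 0.3–2, learning scores −45..+5%).  Clamping
slightly attenuates extreme latents but keeps every subject's truth
physical.  Per-subject seeds are spawned deterministically from the
population seed, so any subject can be regenerated in isolation.

### What the generator does not emulate

Realistic head anatomy and sensor geometry, eye-blink/cardiac
artifacts, multi-muscle EMG crosstalk, within-subject session-to-
session variability, and the HPI-coil artifact that motivates the
wide experimental notch.  Trial-to-trial γ-power variability has no
published reference value; it is exposed as the carrier/noise
structure rather than asserted.  Passing recovery tests therefore
demonstrates the *pipeline's* correctness under controlled
conditions, not field performance on real recordings.

## Validation studies and problem sizes

`gammaflow.validation` runs four recovery studies; the acceptance
script reruns them from scratch:

* EMG onsets: 4 sessions × 56 Go trials at EMG SNR 5; ≥ 95% of
  detected onsets within ±30 ms of truth.
* Beamformer: 50 runs, 5×5×5 grid, one random point source each,
  array SNR 10, 20 trials; peak of the unit-noise-gain variance map
  within one grid step (per axis) of truth in ≥ 95% of runs; unit
  gain holds to 10⁻⁸ for every weight vector.
* Peak frequency: 20 subjects with true slow-γ peaks uniform in
  35–57 Hz at SNR 5, full chain; median |error| ≤ 1 Hz (the grid
  spacing).  Subjects whose true peak falls inside the 49–51 Hz notch
  contribute larger errors by construction; the median absorbs them.
* Full chain: 25 replicates of 40 subjects with latent correlation
  0.65 between slow-γ peak frequency and SICI ratio, measured
  end-to-end at reduced size (400 Hz, 18 sensors, 3×3×3 grid, 25 of
  the task's 70 trials, peak search restricted to the central 9-voxel
  ROI — the analogue of confining the real analysis to M1 virtual
  sensors; measurement error at this size is small next to
  between-subject variance); in ≥ 80% of replicates the recovered r
  is within ±0.2 of 0.65 *and* the Bayes factor reaches an H1
  category.  A null population (latent correlation 0) must yield a
  median BF₁₀ below 1.

These sizes keep a full sweep within minutes on one CPU core while
the estimated rates and medians remain stable.

## Known limitations

* The EEG-style channel-space path shares the MEG machinery; no
  re-referencing or scalp interpolation is implemented.
* The stretched-beta prior quadrature is accurate for κ ≤ 1; κ > 1
  puts integrable singularities at ρ = ±1 that fixed Gauss–Legendre
  handles less precisely.
* GESD inherits the usual masking behaviour when contamination
  approaches the 20% cap.
* The dependent correlation comparison needs the non-shared-variable
  correlation for exact calibration; the 0 default is conservative
  for positively related measures.
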
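# Methods

This note documents the models and numerical choices behind
`pulsechain`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Signal model

All waveforms are uniformly sampled (`UniformSignal`: values, rate `fs`,
start time `t0`; sample *k* at `t0 + k/fs`, seconds everywhere). Beat
detections are strictly increasing event times (`BeatTrain`);
inter-beat durations are stamped at the beat *ending* each interval
(`IntervalSeries`), so the cumulative sum of durations reconstructs the
beat times exactly. On-disk format is plain CSV (`time,value`), with an
auto-detected single header line; millisecond timestamps can be
converted at read time.

## Wavelet band filtering

The maximal-overlap (undecimated) DWT is used because it is
shift-invariant and keeps every coefficient sequence at the input
length, so whole dyadic bands can be kept or dropped and the signal
re-assembled exactly. The transform is the standard pyramid with the
orthonormal filter pair rescaled by 1/√2 and filters upsampled by
2^(j−1) at level j; PyWavelets supplies the filter taps only.

* **Boundary handling** is circular. This keeps reconstruction exact to
  machine precision (verified < 1e−12 relative error) at the cost of
  wrap-around artifacts in the first/last `(2^L − 1)(taps − 1)` samples,
  which are flagged at debug level. Coefficients are kept or dropped
  wholesale; no thresholding is applied.
* **Nominal bands**: detail level j of a signal at `fs` covers
  `[fs/2^(j+1), fs/2^j]` Hz; the level-L approximation covers
  `[0, fs/2^(L+1)]`.
* **PPG preset** (25 Hz): coiflet-1 — its shape suits a pulse wave with
  systolic and diastolic phases — 4 levels, keep D3–D4 =
  0.78125–3.125 Hz. Printed as 0.78–3.12 after two-decimal *truncation*
  (not rounding), and quoted in bpm as 47–187 (round(60 × truncated
  edge)).
* **ECG preset** (130 Hz): symlet-4 (QRS-like), 10 levels, reject D1–D2
  (16.25–65 Hz noise) and A10 (< 0.064 Hz wander).
* **Other sampling rates**: the decomposition depth and kept/rejected
  levels are re-derived so the same absolute bands are retained (PPG:
  dyadic bands overlapping 0.78–3.12 Hz; ECG: approximation pushed below
  0.064 Hz, details at/above 16.25 Hz dropped), with a warning, since
  dyadic edges move with `fs`.

Band-edge leakage is real: a sharp physiological QRS keeps ~94% of its
correlation with the original after the 16.25–65 Hz band is dropped; a
QRS-like train whose content is confined to 5–15 Hz keeps > 99%.

## Amplitude demodulation

All three algorithms divide the waveform by a strictly positive local
amplitude estimate, so signs and zero-crossing sample indices are
preserved — the property that makes demodulation safe ahead of beat
timing. The analytic-envelope (Hilbert) method is the default: it is
parameter-free and flattens an AM envelope with ratio 3 to within ~3%.
The windowed alternatives need an odd `window_len` (default 125 samples
= 5 s at 25 Hz, ≥ 3 pulse cycles at 40 bpm); the online algorithm's
extrema gate `P` defaults to 0.3. The gate biases the divisor where the
amplitude ramps within a window (small-side extrema fail the
`P·(max−min)` test), so its output envelope is flat only to ~25% — one
reason the envelope method is the default. Degenerate inputs (zero
local SD, vanishing envelope, extremum-free windows) fall back to
epsilon-guarded divisors and are logged, never raised mid-signal.

## Beat detection

* **Pan–Tompkins (ECG)**: five-point derivative, squaring, 150 ms
  moving-window integration. The integration is *centred* so the
  fiducial has no group delay; the classic band-pass front end is
  omitted because the wavelet filter has already shaped the band. Dual
  adaptive thresholds (signal/noise running estimates with 0.125/0.875
  smoothing), search-back at 1.66× the 8-beat running RR average with a
  halved threshold, a 200 ms refractory period, and a T-wave test
  (candidates within 360 ms need at least half the previous beat's
  maximum slope). Fiducials are refined to the ECG maximum within
  ±50 ms.
* **PDA**: strict local maxima gated at 0.8× the rolling ±1 s maximum.
  The gate's referent is a design choice — after demodulation the
  envelope is near unity, which is what makes a relative gate
  meaningful. Conflicts within 0.3 s keep the larger peak.
* **AMPD**: per segment, the local-maxima scalogram over scales
  1..⌈len/2⌉−1 is built after linear detrending; the scale minimising
  the not-a-maximum count is selected and samples that are maxima at
  every smaller scale are peaks. The scalogram is quadratic in segment
  length, so the signal is split into segments expected to hold ~30
  pulses (using a spectral rate estimate in 0.5–3.5 Hz), overlapping
  50%; duplicates within 0.1 s keep the earlier index.
* **SSF**: the slope sum `SSF[i] = Σ max(Δx, 0)` over a trailing 128 ms
  window accentuates upstrokes. The signal is reflected upside-down so
  the onset of the reflected upstroke lands at the systolic peak rather
  than the pulse foot. The initial threshold is the mean SSF over the
  first 10 s (a threshold must live on the SSF scale); after each pulse
  it becomes 40% of that pulse's SSF maximum; refractory 0.3 s. The
  reported time is the signal maximum from one SSF window before the
  onset to 0.3 s after it — the small look-back keeps SSF fiducials
  aligned with PDA/AMPD to within one sample, so the three detectors
  are interchangeable on clean data (≥ 99% agreement).
* **Sub-sample refinement**: detected peaks are refined on a 1 kHz cubic
  spline grid in a ±0.12 s neighbourhood. A 25 Hz grid quantises beat
  times to 40 ms, which alone costs ~2% RRMSE; local refinement
  recovers the precision of globally upsampling the record at a tiny
  fraction of the cost (and keeps AMPD feasible).

## Interval post-processing

Repairs conserve total summed duration exactly (merging adds durations,
splitting halves them), so the repaired series spans the same time.

* **Physiological screening** (0.3–1.5 s = 200–40 bpm): a short interval
  marks its ending beat as spurious and merges into the following
  interval (the preceding one if last); a long interval suggests a
  missed beat and splits in half. One left-to-right pass; a merged value
  is re-examined in place, but intervals still out of bounds after the
  pass (e.g. halves of a very long gap) are logged, not re-processed.
* **Local-statistics repair**: centred 25-sample moving mean and SD
  (truncated at the edges, computed once on the input); samples above
  mean + 3 SD split, below mean − 3 SD merge forward — the same repairs
  as screening. The two-sided Gaussian tail at 3 SD is 0.0027, so valid
  samples are rarely touched (< 0.5% measured on clean Gaussian
  series). Zero-SD windows treat every sample as inside the band.
* **Uniform resampling**: cubic spline of (anchor time, duration) onto a
  10 Hz grid, zero-phase FIR low-pass, decimation to 1 Hz, never
  extrapolating beyond the anchor span. The filter is a Kaiser-window
  design with a 0.1 Hz transition centred on the 0.5 Hz physiological
  cutoff (60 dB stopband from 0.55 Hz; applied forward-backward, so
  attenuation doubles); taps are capped for very short series. DC gain
  is exactly 1, so a constant series passes through unchanged.
* **AR correction**: a 25-sample window slides over the 1 Hz series; a
  Burg AR(8) fit on the mean-removed window predicts the next sample,
  which is replaced when it deviates by more than one innovation SD.
  Two calibration choices matter and were settled empirically:
  (1) windows are fit on the *observed* series (open loop). Feeding
  corrected values forward lets the model lock onto its own
  extrapolation — on clean data the closed loop replaced ~90% of
  samples and tripled the recovery error, while open loop is nearly
  neutral (≈ +0.5 pp) and still snaps isolated spikes back to within a
  few SD of the uncontaminated series. (2) the innovation SD carries a
  √(window/(window−order)) small-sample factor so the 1-SD gate refers
  to out-of-sample prediction error; the raw order-8-on-25-samples fit
  underestimates it by ~40%. The window (25) is fixed; order 8 balances
  spectral flexibility against what 25 samples can support.

## Synthetic ground truth

The generator emulates a seated laboratory recording: an IPFM beat
process with instantaneous rate
`r(t) = HR + A_LF·sin(2π·0.1·t) + A_HF·sin(2π·0.25·t)` (defaults 70, 3,
2 bpm) emits a beat at each integer crossing of `∫r/60`; beats get
Gaussian timing jitter of SD 5 ms, a deliberately low-end stand-in for
the broadband beat-to-beat variability real sinus rhythm carries beyond
two deterministic tones (a jitter-free two-tone series is degenerately
predictable and misrepresents how prediction-gated corrections behave).
PPG pulses are a systolic Gaussian lobe with a diastolic bump at 0.35
amplitude, peaking a constant 0.25 s pulse-transit delay after each
R-peak; the ECG template is a narrow biphasic QRS with small P/T lobes.

Artifact regimes (severity is a single scalar on regime-nominal
amplitudes; Gaussian sensor noise at 0.05·severity·RMS rides on all of
them; severity 0 is the identity):

* **light** — additive square wave, 10 s half-period (lamp switching);
* **tap** — biphasic spikes at 1 s periods for the first half of the
  record and 2 s for the second (150 + 75 events over 300 s), each
  followed by a damped ~2.5 Hz ring over ~0.3 s. The ring matters: the
  mechanical transient of a real tap disturbs optical coupling for a few
  tenths of a second and has energy inside the pulse band, whereas a
  one-sample spike is broadband and the band filter would remove it
  entirely;
* **arm** — multiplicative envelope `1 + severity·sin(2πt/20)` (20 s
  swing cycle, hydrostatic pressure) plus additive 0.05 Hz wander;
* **breath** — additive baseline at 5 breaths/min for the first half and
  30 for the second; the physiological side of breathing (rate
  modulation itself) belongs in the beat process via the HF modulator,
  not in the waveform.

What the generator does **not** emulate: pulse-shape morphology changes,
sensor saturation/clipping, skin-tone and perfusion effects, clock drift
between devices, ectopic beats, or the step-locked artifacts of walking
and running. Passing tests therefore demonstrate that the chain
recovers beat timing and variability spectra under controlled additive,
multiplicative and timing disturbances — not that it handles every
failure mode of real wrist recordings.

## Evaluation

DTW uses the classic dynamic program with cost `|a_i − b_j|`, unit
weights, steps (i−1,j), (i,j−1), (i−1,j−1), no windowing constraint
(series are short, a few hundred beats), ties broken toward the
diagonal during backtracking; durations enter in seconds, without
normalisation. The aligned Pearson r counts every path pair once.
RRMSE is `100·‖PRV−HRV‖₂/‖HRV‖₂`; the cross-recording summary is the
RMS of individual RRMSEs, which by the RMS–AM inequality never falls
below their mean. Welch PSDs use 30 s Hamming segments, 25-sample
overlap, per-segment mean removal, one-sided densities.

Both uniform series are built on one shared 1 Hz grid restricted to the
overlap of their anchor spans, so RRMSE is well defined. The constant
pulse-transit delay shifts PRV anchors ~0.25 s relative to HRV; the
variability waveform changes slowly compared to that, contributing well
under 1% to the measured RRMSE.

## Problem sizes

Simulated recordings are 300 s (the duration of one laboratory
activity); detector comparisons use all three PPG algorithms; the
artifact-robustness summary uses 10 independent seeds per regime; the
DTW oracle check uses 200 random pairs of lengths ≤ 8 (exhaustive path
enumeration grows combinatorially); reconstruction checks use 20 random
signals per wavelet.

## Known limitations

* The AMPD rate estimate assumes a dominant spectral line in
  0.5–3.5 Hz; on signals that are mostly artifact it can mis-size
  segments.
* Circular wavelet boundaries assume the record's ends are
  unremarkable; a large step at either end leaks into all levels.
* The SSF look-back window and the PDA gate referent are
  interpretations (documented above); both were chosen so the three
  detectors emit comparable fiducials.
* Screening is a single pass by design; pathological inputs (gaps of
  many seconds) remain flagged-but-unrepaired in the log.
* The AR stage assumes the 1 Hz series is locally stationary over 25 s;
  genuine rapid physiological shifts can be "corrected" away — on clean
  data this costs ~0.5 pp RRMSE, which is why the stage is worthwhile
  only for corrupted recordings.
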
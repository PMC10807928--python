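# Methods

`voleabr` analyzes small-rodent auditory brainstem responses (ABRs) and the
acoustic cues available to the animal: monaural wave I–IV quantification,
the binaural interaction component (BIC/DN1) across interaural time
differences (ITDs), evoked-potential audiograms, and head-related transfer
function (HRTF) cue extraction. Because no epoch-level recordings are
distributed with the group statistics the package is built around, a
synthetic-session generator reproduces the statistical structure the
analysis assumes, and every stage is validated by parameter recovery
against that generator.

## Signal model and ABR quantification

An epoch is 12 ms of scalp voltage sampled at 97 656.25 Hz, stimulus-locked,
with 500–1000 repetitions per condition. The analysis path is:

1. **Band-pass** 50–3000 Hz, 2nd-order Butterworth. Applied zero-phase
   (forward–backward) by default so wave latencies carry no group-delay
   bias; this doubles the effective order, which we accept and state. A
   causal single-pass mode is available for data recorded through causal
   hardware filters.
2. **Average** epochs pointwise, then subtract the whole-trace mean
   (baseline normalization). The subtracted offset is retained.
3. **Peak quantification.** Each wave is the largest local maximum (SciPy
   prominence ≥ a criterion, default 2× the RMS of the final 2 ms of the
   trace) inside a per-wave search window; windows default to the published
   group latencies ±0.6 ms and may overlap, so assignment runs in wave
   order with strictly increasing latencies, ties breaking toward earlier
   latency. Amplitude is peak minus trough, where the trough is the
   minimum between the wave's peak and the next detected wave's peak
   (trace end for the last wave) — reading "absolute trough" as the
   between-wave minimum, since a global minimum would give all waves one
   shared trough. Latency is time-to-peak.
4. **Annotation.** Automatic peaks can be kept, moved to a sample index
   (re-quantified there), or deselected; troughs are re-derived after any
   edit.
5. **Ear averaging.** Amplitude and latency are averaged per wave across
   ears where both are present; single-ear waves are carried with a flag.

## Binaural interaction component

BIC(t) = binaural(t) − [left(t) + right(t)], computed on
baseline-normalized averaged traces with no time-shifting of the monaural
responses before summation. Under this sign convention the first binaural
deflection, DN1, is negative; we report its magnitude relative to the zero
baseline, so downstream tables are convention-agnostic. DN1 is the most
negative local extremum in a 3.5–8 ms window (bracketing wave IV and the
reported DN1 latencies across ITDs); it is reported absent when no local
minimum exists or its magnitude is below 2× the RMS of the BIC trace
outside the window. The curve of DN1 magnitude and latency is assembled
over the ±2 ms, 0.5 ms-step ITD grid.

## Threshold estimation and audiograms

A level series descends in exact 10 dB steps. An automated observer stands
in for the study's two trained human raters: the score is the peak-to-peak
voltage in the 1–8 ms response window divided by a noise peak-to-peak
estimate from the final 2 ms of the same trace, and a response is present
when the score reaches the criterion (default 2.0). Two details matter:

- **Window-length correction.** The expected extreme range of n effectively
  independent Gaussian samples grows as √(2 ln n), so a raw 7 ms/2 ms
  peak-to-peak ratio of pure noise averages ≈1.5 and false-positives ~15%
  of the time at criterion 2.0. The noise estimate is therefore scaled by
  √(ln n_resp / ln n_noise) with n = 2 · 3000 Hz · T (the filter's upper
  edge as the noise bandwidth), which restores the criterion's "twice the
  noise floor" meaning and brings the false-positive rate to ~5%.
- **Midpoint rule.** Scanning from the highest level, the threshold is the
  midpoint of the last present and first absent levels (60 dB present,
  50 dB absent → 55 dB SPL); with levels on multiples of 10 the estimate
  always ends in 5. All-present series are censored `below_min`,
  all-absent `above_max`. A response re-appearing below an absence is
  non-monotone: a warning is raised and the first absence from the top is
  used, matching the stop-at-first-absence acquisition procedure.

Audiograms collect per-frequency thresholds over the tested set
{1, 2, 4, 8, 16, 24, 32, 46} kHz; the best (lowest-threshold) frequency
breaks ties toward the lower frequency, a tie-break the 10 dB quantization
makes occasionally necessary. Clicks are handled as an extra tag through
the same path.

## HRTF cues

Recordings are 128k-point exponential sine sweeps (250 Hz–20 kHz, −15 dBFS,
44.1 kHz), five repeats per position, on a horizontal grid of 19 azimuths
(−90°…+90°, 10° steps; the rig's two 180° axes offer 19 × 19 = 361
positions, of which the horizontal 19 are measured). Processing:

- **Deconvolution.** The inverse filter is the amplitude-compensated
  time-reversed sweep, realized in the frequency domain as the regularized
  matched inverse conj(S)/(|S|² + ε·max|S|²), ε = 10⁻⁶. In-band (0.5–18
  kHz) systems are recovered to well under 1%.
- **Gain spectra.** 512-point FFT magnitude of the impulse response,
  rectangular window starting 1 ms before the impulse peak (≈11.6 ms at
  44.1 kHz). HRTF gain = animal spectrum − no-head calibration spectrum
  (dB). Repeats are averaged in the time domain (they share one clock).
- **Smoothing.** Fractional-octave (default 1/48) Gaussian kernel in log₂
  frequency, σ = fraction/2, averaging powers with per-bin normalized
  weights so flat spectra pass unchanged. On the 512-point grid the kernel
  only acts above a few kHz, as with typical acoustics software.
- **DTF.** Per frequency, the across-position mean gain is subtracted; the
  DTFs average to 0 dB by construction.
- **ILD.** Right-ear gain minus left-ear gain per position (dB).
- **ITD.** Lag of the maximum of the left/right impulse-response
  cross-correlation, minus the (zero) autocorrelation peak lag, with
  3-point parabolic sub-sample interpolation; positive = right ear leads.
  On synthetic scenes the delay curve is recovered to ≤0.25 sample with
  interpolation (≤1 sample without).
- **Rigid-head prediction.** Maximal ITD = (pinna width + inter-pinna
  distance)/c with c = 343 m/s, reported in µs; the inverse returns the
  acoustic path length. The simple quotient is used (no wrap-around term).
  Effective pinna diameter is the equal-area circle of an elliptical
  aperture, √(length · width) — this reproduces the published per-sex
  diameters from the published length/width means to ~0.1 mm.

## Synthetic-session generator

The generator's defaults are the study conditions; its parameters are the
published group statistics (means ± standard errors with group sizes) for
male and female prairie voles, stored in `voleabr.reference`.

- **Wave templates.** Each wave is a positive-going Gaussian of height
  `amplitude_uv` at `latency_ms` with σ = `width_ms` (default 0.15 ms).
  Troughs emerge from superposition and the band-pass. The width is not a
  published quantity; 0.15 ms keeps all four waves resolvable at the
  published latencies and makes the filtered peak-to-trough of the
  averaged trace match the generating amplitude to ~3%, so the amplitude
  parameter means what the pipeline measures. Waves II/IV are
  positive-going per the standard montage polarity.
- **Noise.** Per-epoch additive white Gaussian noise, default SD 5 µV for
  wave/BIC sessions (≈0.2–0.3 µV residual after 500–1000 averages —
  a realistic averaged-noise floor); threshold series use 0.5 µV with 400
  epochs, reflecting the cleaner high-SNR regime threshold reads assume,
  which puts reliable detection within ~4 dB of the true threshold (the
  10 dB ladder's quantization limit). The band-limiting of real
  amplifier noise is left to the downstream filter.
- **Level growth.** Amplitude scale is linear in dB between the true
  threshold (scale 0) and 90 dB SPL (scale 1, saturated); only the
  stepping procedure, not the growth law, is constrained by the source
  material.
- **Between-animal draws.** Each animal draws one standard-normal deviate
  per parameter family (wave amplitudes, wave latencies, BIC amplitudes,
  BIC latencies), scaled by √N·SE per entry. Marginals are
  Normal(mean, √N·SE); the shared deviate preserves the latency ordering
  I<II<III<IV and couples the BIC curve across ITDs the way animals are
  coupled. Amplitudes are clipped at zero.
- **Binaural sessions.** Binaural epochs are the sum of the two noiseless
  monaural templates plus an injected negative Gaussian DN1 (σ = 0.25 ms)
  whose magnitude/latency follow the per-ITD table, plus fresh noise —
  exactly additive when the DN1 amplitude is zero. Two DN1 presets exist:
  the verbatim per-sex tables (used for parameter recovery), and a
  canonical symmetric curve (linear-in-|ITD| regression of the
  symmetrized table) whose amplitude is strictly maximal and latency
  strictly minimal at 0 ITD, for qualitative-shape work; the raw male
  amplitude row peaks off-zero within its standard errors, so it cannot
  serve that role.
- **Acoustic scenes.** A rigid-head model: interaural delay =
  max_itd · sin(azimuth) (exact fractional delays applied in the frequency
  domain), and a first-order high-shelf level shadow reaching ±max_ild/2
  dB per ear above a corner frequency (defaults 18 dB total, 4 kHz)
  laterally. The calibration recording sees only the common bulk delay and
  is head-independent. Delays and ILDs are odd in azimuth by construction.

**What the generator does not emulate:** cochlear and middle-ear
nonlinearity, level-dependent latency shifts, non-Gaussian or non-white
physiological noise, stimulus artifacts, electrode drift, pinna-specific
spectral notches, and room reflections. Passing recovery tests therefore
demonstrates that the analysis is correct and unbiased under the stated
statistical model, not that it is robust to every artifact of real
recordings.

## Problem sizes

Recovery checks run at the study's cohort scale: 9 simulated animals × 500
epochs/ear for monaural waves, 9 animals × 1000 epochs/condition across
the 9-point ITD grid for the BIC, 400-epoch level series over the 8
frequencies for audiograms, and full 128k-point sweeps for the HRTF scene.
These complete in seconds to a couple of minutes on one CPU; unit tests use
smaller cohorts of the same structure.

## Known limitations

- The automated observer is calibrated (≈5% false-positive rate at
  criterion 2.0) but is not a validated stand-in for trained human raters
  on real, artifact-laden traces.
- Threshold estimates inherit the ±5 dB half-step quantization of the
  descending 10 dB procedure; censored results carry no partial
  information.
- Mixed-effects modeling and multiple-comparison contrasts are out of
  scope by design; the tidy CSV exports are the interface to external
  statistical tools.
- HRTF processing covers the horizontal plane only (as measured); the
  grid types support elevation but no vertical-plane pipeline is provided.
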
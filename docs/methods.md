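# Methods

This note documents the models, parameter defaults, numerical choices and
limitations of the `fnirspipe` pipeline and its forward simulator.

## Signal model

The package targets continuous-wave, single-channel fNIRS: one
source–detector pair, two wavelengths (660 and 880 nm by default), measuring
relative hemodynamic changes over one cortical site. Under the modified
Beer–Lambert law, the change in optical density at wavelength λ is

    dOD(λ, t) = [ε_HbO(λ)·ΔHbO(t) + ε_HbR(λ)·ΔHbR(t)] · d · DPF(λ)

with ε the decadic molar extinction coefficients (cm⁻¹ M⁻¹), `d` the
source–detector distance and DPF the differential pathlength factor.
Scattering losses are assumed constant over the recording, so they cancel in
OD *changes*; there is no partial-volume correction and DPF is a scalar per
wavelength. With two distinct wavelengths the relation is an exactly
invertible 2×2 linear system per sample; its condition number is computed,
logged in the output container, and enforced against a configurable bound
(default 10³), which rejects degenerate wavelength pairs.

Defaults: `d = 3.0 cm`, `DPF = 6.0` at both wavelengths — common
adult-forehead conventions; both configurable. Extinction coefficients ship
as a delimited data file (`src/fnirspipe/data/extinction_hb.csv`)
interpolated from the standard Gratzer/Kollias compilation; users can
substitute their own table.

## Preprocessing

**Optical density.** `OD = -log10(I/I0)` with `I0` the mean intensity over
the full recording (the Homer convention); a window-referenced `I0` is
available for baseline-referenced OD. OD is invariant to rescaling the
raw intensity, so detector gain is irrelevant downstream.

**Motion-artifact detection** operates on OD, where the 0.3 amplitude
threshold is dimensionally meaningful. Over every sliding window of 0.2 s
the peak-to-peak excursion is compared against (a) the absolute threshold
0.3 OD and (b) 10× a robust scale of the series' sample-to-sample
differences. The robust scale is 1.4826×MAD of the first differences rather
than their raw SD so that the noise estimate is itself artifact-resistant: a
handful of artifact samples barely move the median where they would dominate
a standard deviation. Flagged windows are dilated by ±0.1 s and OR-ed across
wavelengths, because motion is common-mode — both chromophore estimates
should share one mask. Detection is invariant to adding a constant to the
signal and monotone in the amplitude threshold.

**Spline correction** follows the MARA approach: within each flagged
segment a cubic smoothing spline is fit and subtracted, removing the
artifact's trajectory. The "tension" 0.99 is interpreted as the 0..1
smoothing parameter `p` of the classical smoothing-spline objective
`p·Σ(y−f)² + (1−p)·∫f″²` and mapped to the regularization weight
`λ = (1−p)/p` of `scipy.interpolate.make_smoothing_spline`, evaluated on
the **sample-index grid**. Evaluating on the index grid (rather than
seconds) makes the penalty scale with the sampling interval so the spline
tracks even single-sample spikes; on a seconds grid at 10 Hz the same `p`
over-smooths sharp transients and leaves ~35 % of a spike behind.
Segments shorter than 4 samples fall back to linear-trend removal.

After subtraction the series is reassembled piece by piece: each piece is
shifted by a constant so the mean of a short boundary window (one third of
the piece, capped at 2 s) matches the most recent **clean** level. Clean
pieces re-level against the clean piece *before* the artifact, bridging the
gap — this removes persistent baseline steps instead of freezing them into
the record, and avoids chaining offsets through the noisy artifact
residual. Consequently clean samples are preserved exactly in shape but may
carry a constant per-piece offset; the band-pass removes constants, so the
downstream analysis is unaffected. Segments touching a recording edge are
re-leveled one-sidedly and logged.

**Band-pass.** 3rd-order Butterworth, 0.01–0.1 Hz, applied
forward–backward (`sosfiltfilt`; zero phase, effective 6th order), with
odd-reflection padding of `1/low_cutoff` seconds. Recordings shorter than
one pad length are rejected rather than silently truncated. Measured
response (sinusoid regression after edge discard): 0.999 amplitude at
0.05 Hz, <10⁻⁵ at 1.1 Hz, cross-correlation peak at lag 0.

## Epoching and amplitude summaries

Epochs are cut at task-onset markers with a default window of −5…+25 s,
baseline-corrected to the pre-onset mean, and averaged pointwise with SEM.
Partial epochs at recording edges are dropped (never zero-padded), with a
logged count. Scalar summaries per run: mean ΔHbO from 5 s post-onset to
block end (skipping the hemodynamic rise) and over the final 10 s of each
rest period (avoiding the post-task undershoot); both windows configurable
and recorded in the output. Because the paired rest-vs-task difference is
invariant to DC offsets, the arbitrary OD reference does not bias it.

## Statistics

Paired-samples t-test on per-run (or per-participant) scalars:
`t = mean(d)/(sd(d)/√n)` with `df = n−1`, two-tailed p from Student's t,
and paired Cohen's `d = mean(d)/sd(d) = t/√n`. α = 0.05, no
multiple-testing correction. The standard error of `d` is reported via the
first-order approximation `√(1/n + d²/2n)`; the exact sampling variance of
a standardized paired difference is not tractable in closed form and other
software uses different approximations, so this value is informational.
Zero-variance differences raise an error (t undefined). Calibration is
verified by simulation: the null rejection rate over 2000 replicates sits
inside the 99 % binomial band around 0.05, and power rises monotonically
with injected effect size.

## Signal-to-noise ratio

Published SNR figures for this device class rarely state their formula, so
the package ships three documented definitions behind one interface and
records the definition in every report; no attempt is made to reproduce any
particular published value. Default (`amplitude_ratio`): peak-to-peak of
the baseline-corrected block average, divided by the SD of the rest-period
**residual** — the recording minus the evoked estimate obtained by tiling
the block average back onto the session at each task onset, de-meaned per
rest segment. Subtracting the evoked estimate matters: the hemodynamic tail
spills into rest periods, and without removing it the "noise" term is
dominated by signal, making the ratio insensitive (even inverted) with
respect to true noise level. With it, the measured SNR is scale-invariant
and strictly decreasing in injected noise amplitude. `power_ratio` squares
the amplitude ratio; `db` is 20·log₁₀ of it.

## The simulator

The generator inverts the analysis chain so every intermediate has exact
ground truth:

- **Design.** Alternating rest/task markers; task onsets at
  `rest + k·(rest+task)`. Paradigm defaults: finger tapping 15 s rest /
  15 s task × 5 blocks; 1-back and 2-back 16 s rest / 20 s task × 6 blocks;
  the self-paced alternate-uses task is approximated by fixed 30 s
  pseudo-blocks with its 13 s rests. A trailing rest closes each session so
  the last block can be epoched. Sampling rate defaults to 10 Hz, a
  realistic figure for a photodiode device of this class.
- **Evoked response.** Canonical double-gamma HRF (gamma densities of shape
  6 and 16, unit scale, undershoot ratio 1/6; peak ≈ 5 s, unit-normalized,
  <5 % of peak by 25 s) convolved with the task boxcar. The convolved
  regressor is scaled to unit peak over the session, so
  `hrf_amplitude_hbo` (default 1 µM) *is* the peak evoked ΔHbO;
  `hrf_amplitude_hbr` defaults to −1/3 of it.
- **Noise**, added linearly in OD space (which keeps ground-truth
  bookkeeping exact): sinusoids at 1.1 Hz (cardiac, 0.010 OD), 0.3 Hz
  (respiratory, 0.005 OD) and 0.1 Hz (Mayer waves, 0.003 OD) with random
  phases per wavelength; white sensor noise (0.002 OD); polynomial drift
  (5×10⁻⁵ OD/s + 10⁻⁷ OD/s²). Amplitudes were chosen once as realistic
  relative to a 1 µM evoked response on a 3 cm channel; the Mayer component
  deliberately sits *inside* the analysis band, as it does in real data.
- **Artifacts**: Gaussian spikes (width ≈ duration/4) and persistent steps,
  identical across wavelengths, with sample-exact ground-truth ranges.
- **Intensity** is derived last, `I = I0·10^(−OD)`; a configuration whose
  excursions would underflow intensity to a non-positive float is rejected
  with a diagnostic.
- **Determinism.** One root seed; per-component RNG sub-streams are spawned
  deterministically, so changing one noise amplitude never reshuffles the
  others. Identical config + seed ⇒ bit-identical output.

A companion behavioral generator produces per-participant accuracy/RT pairs
for two conditions with configured shifts and between-subject noise,
truncated to valid ranges (accuracy ∈ [0,1], RT > 0) — near the bounds the
realized shift is attenuated by truncation.

What the simulator does **not** emulate: optode-skin coupling changes,
serially correlated (1/f) physiology, scalp/systemic layers that would
require short-separation regression, multi-channel geometry, or photon
transport. Passing recovery tests on this forward model therefore
demonstrates internal consistency of the chain — not performance on real
tissue.

## Amplitude-recovery metric

Recovery studies compare the pipeline's block average against the identical
epoch/baseline/average procedure applied to the noiseless ground-truth ΔHbO
series. The recovered amplitude is the slope of a least-squares regression
(with intercept) of the pipeline block average onto the ground-truth block
average: with intercept because the high-pass stage shifts the filtered
trace by a constant relative to the unfiltered truth, and regression rather
than the maximum because a max operator is biased upward by in-band noise
(≈ +11 % at default noise levels). A peak-based estimator remains available
for noiseless checks. Measured performance: recovery within 2 % with noise
off (the residue is harmonic attenuation at the band edges), and within
10 % — in practice ≈ 2 % in the mean — over 20 seeds at default noise.

## Problem sizes

Validation studies use 50 sessions for the artifact benchmark, 20 seeds for
amplitude recovery, 2000 replicates for null calibration and 500 per point
for the power curve — sizes at which the binomial/seed variability is well
inside the asserted margins.

## Known limitations

- Single channel only; no short-separation regression, wavelet or PCA
  motion correction, and no GLM/deconvolution — block averaging is the only
  response estimator.
- ΔHbR is computed and reported alongside ΔHbO, but with only two
  wavelengths its estimate inherits any extinction-table error directly.
- The SE reported for Cohen's d is an approximation (above).
- File formats are package-specific delimited text; SNIRF export is
  deliberately out of scope for now.
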
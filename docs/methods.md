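# Methods

## Signal model and assumptions

The pipeline treats the steady-state BOLD response to a block paradigm with
equal on/off durations (trial frequency f ∈ {0.05, 0.10, 0.20, 1/3, 0.50}
Hz) as a periodic signal riding on a baseline of 1000 arbitrary units, with
additive linear drift and noise:

    s_v(t) = B · [1 + 0.01 · a_d · w(t − τ_d)] + drift(t) + ε_v(t)

per voxel v in depth bin d. The oscillation waveform w has **unit
fundamental amplitude** by construction, so a_d is directly the per-depth
fundamental amplitude in percent signal change. Two waveforms are
available: a pure sinusoid at the trial frequency (the default — the
steady-state abstraction the depth analysis assumes) and an HRF-convolved
boxcar rescaled to unit fundamental (which adds the harmonic structure and
initial transient of a linear-convolution response). Control compartments
carry baseline, drift and noise only; CSF is a separate compartment with
its own amplitude and delay, never a depth bin. Depth index 0 is the
white-matter interface and the maximum index the pial surface.

All analysis operates per run on the TR grid (TR = 0.5 s, 480 volumes by
default, optionally 520 with a 20-s lead-in rest block; t = 0 is the first
retained volume — dummy scans are never represented).

## Stage conventions and numerical choices

**Percent signal change.** Per voxel: least-squares linear detrend, divide
by the temporal mean, ×100, mean-centre. The slope fit inevitably absorbs
a sliver of the lowest-frequency fundamental (a 0.05-Hz run holds only 12
trial periods), which bounds "noiseless" recovery at roughly the 0.5%
level for the default run length; this is a property of linear detrending
itself, and recovery is exact to machine precision when detrending is
skipped.

**Transient removal.** Everything before the trial onset closest to the
65-s mark is discarded; ties are broken toward the earlier onset (retains
more data). The remainder is truncated to an integer number of trial
periods, so every stimulus fundamental falls on an exact FFT bin and the
rectangular window is leakage-free there.

**Spectra.** One-sided amplitude spectra are calibrated so a sinusoid of
peak amplitude A reads A in its bin (2|X_k|/N, with DC and Nyquist
halved). Voxel spectra are averaged as magnitudes — an out-of-phase voxel
pair averages to its common amplitude rather than zero, matching the way
no-task noise floors are built; complex averaging is available behind a
switch. Normalization divides by the same-session 0.05-Hz reference
amplitude: the S1 spectrum by the S1 reference, M1 and both control ROIs by
the M1 reference. Noise floors are mean no-task magnitude spectra; the
floor for an n-run average is the single-run floor divided by √n, and for
white noise of SD σ the per-bin expectation is σ√(π/N) (used as a test
oracle). The DC bin is excluded from floors and normalization.

**Trial averaging.** Trials are one on+off period, partitioned at the
detected hand-motion onsets when a glove trace is available, else at the
nominal paradigm onsets. Means are taken voxel-by-voxel and run-by-run,
then across runs, then across voxels; the 95% CI half-width per timepoint
is 1.96·SD(voxel means)/√n_voxels (normal approximation across voxels).

**Kinematics.** Savitzky–Golay window 7 samples (~0.47 s) and polyorder 3
at 15-Hz sampling: short enough to pass 2-Hz flexion, long enough to
suppress sensor noise. Note the derivative gain of this filter at 2 Hz is
~0.9, so derivative *amplitudes* read ~10% low; block detection and
flexion counting threshold at 20% of the maximum absolute derivative and
are insensitive to this. Sub-threshold gaps shorter than 0.25 s are merged
(a flexion cycle's zero crossings must not split a block) and blocks
shorter than one flexion period (0.5 s) are discarded. Flexion counting
uses hysteresis (re-arm below the mirrored negative threshold) to avoid
double counts. Detected block edges overshoot the true on-block by about
one sample per edge, which biases the grasp-frequency estimate slightly
low for short blocks (1.875 Hz for the noiseless 1-s blocks of the 0.5-Hz
paradigm) while per-block flexion counts remain exact.

**Canonical HRF.** Double gamma with the standard parameter set (peak
delay 6 s, undershoot delay 16 s, unit dispersions, peak:undershoot 6,
32-s kernel), sampled at dt = TR/16 and scaled to unit peak — predictions
are reported as ratios to the 0.05-Hz reference, so kernel scaling
cancels (unit-peak vs unit-integral is recorded here as a convention, not
a result). Resampling to the TR grid takes the microtime sample at each
volume onset; no slice-offset modelling. The resulting 0.5-Hz/0.05-Hz
attenuation is 10^−3.02 and is insensitive to the microtime step, kernel
length and lead-in (verified against an independent reference
implementation of the same kernel).

**Depth analysis.** Per-depth trial means are upsampled 50× by
band-limited (zero-padded spectrum) periodic interpolation — chosen over
splines because the subsequent model is a sinusoid and spline
interpolation of 4 samples/period would inject harmonic bias. The sinusoid
fit solves a + b·sin + c·cos by least squares; phase is reported
delay-signed (a response delayed by τ has phase 2πfτ, delay = phase/2πf)
and a constant input is flagged degenerate rather than raised. Delay
profiles are referenced to the CSF fit and unwrapped marching from the CSF
(pial side) inward, so adjacent-depth jumps exceed π only when the data
demand it — relevant only at 0.5 Hz, where delays approach half a period.

**Amplitude operator f.** The fundamental-frequency Fourier amplitude of
the trial mean. This choice is interpolation-invariant (band-limited
upsampling adds no energy to the fundamental bin), so Eqs. applying f to
the raw or upsampled trial mean give identical results; half the upsampled
peak-to-peak range is available behind a config switch for sensitivity
analysis (it agrees with the fundamental for pure sinusoids up to the
10-ms sampling of the peak). Empty depth bins are reported with zero
voxels and excluded from the cancellation sums with a warning.

## What the generator emulates — and what it does not

The generator reproduces the statistical structure the analysis assumes:
steady-state oscillations whose amplitude rises toward the pial surface,
per-depth delays spanning up to ~0.5 s (M1) / 0.35 s (S1) with CSF
trailing the pial surface, a 10–20-fold amplitude drop from 0.05 to
0.5 Hz (the default frequency scaling 1 / 0.6 / 0.25 / 0.12 / 0.05 — far
above the canonical-HRF prediction, as observed in vivo), white or AR(1)
noise with linear drift, and 2-Hz flexion traces with Gaussian block-edge
jitter (SD 40 ms by default).

It deliberately omits: EPI distortion, motion and physiological noise,
slice timing, multi-subject anatomy, 1/f noise structure, and partial
volume effects. The default geometry uses 12 voxels per depth bin —
fewer than a real upsampled ROI — with a correspondingly low per-voxel
noise SD (0.15%) chosen so the **final-average SNR** (weakest depth after
averaging the default 8 runs at 0.5 Hz ≈ 35, and ≈ 200 at 0.05 Hz) sits in
the regime where the in-vivo responses were reported as clearly separated
from the noise floor. Passing tests therefore demonstrate that the
estimators are unbiased and meet their tolerances *at realistic
final-average SNR*; they do not demonstrate robustness to structured
(physiological, motion-correlated) noise that real data contain.

## Problem sizes

Defaults mirror the study conditions: 480-volume runs at TR 0.5 s, five
frequencies with 1/1/2/4/8 runs, 15 M1 + 7 S1 depth bins. The full default
study simulates and analyzes 16 task runs plus no-task runs in about one
second; the complete test suite runs in a few seconds on one CPU.

## Known limitations

- The grasp-frequency estimate inherits the ~1-sample edge bias of
  derivative-threshold block detection; it is accurate to a few percent
  for blocks ≥ 2.5 s and ~6% low for 1-s blocks.
- Linear detrending biases the 0.05-Hz reference amplitude by ~0.4%
  (default run length), which propagates into normalized ratios.
- Phase unwrapping across depth assumes the true profile varies smoothly
  from the CSF reference inward; a genuine >π jump between adjacent depths
  would be folded.
- The cancellation statistic is reported per ROI×frequency without an
  across-subject level; the pipeline models a single synthetic "subject".
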
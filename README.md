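# boldwave

Analysis pipeline for **stimulus-driven high-frequency BOLD oscillations
across cortical depth**, exercised end to end on synthetic laminar fMRI
sessions.

Block paradigms with equal on/off blocks at 0.05–0.5 Hz drive the BOLD
response of primary motor (M1) and somatosensory (S1) cortex into a steady
state. The package implements every stage needed to characterize those
oscillations:

- **Canonical-HRF predictions** — convolving the paradigm boxcar with the
  standard double-gamma hemodynamic response function h(t) =
  Γ(t; 6, 1) − Γ(t; 16, 1)/6 predicts the steady-state fundamental
  amplitude at each stimulus frequency; the kernel acts as a steep low-pass
  filter.
- **Dataglove kinematics** — motion blocks and individual 2-Hz finger
  flexions are detected from 15-Hz joint-angle traces by thresholding the
  Savitzky–Golay-smoothed first derivative; the grasp frequency is
  flexions / detected on-block duration.
- **Steady-state ROI analysis** — voxelwise linear detrend → % signal
  change, removal of everything before the trial onset closest to the 65-s
  mark, one-sided amplitude spectra (sinusoid-peak calibration, magnitudes
  averaged across voxels), normalization to the same-session 0.05-Hz
  reference, no-task noise floors scaled by 1/√(runs), and trial averaging
  with across-voxel 95% CIs.
- **Depth-resolved analysis** — per-depth trial averages S_d (7 bins in
  S1, 15 in M1), 50× band-limited upsampling, least-squares sinusoid fits
  for amplitude and phase, delays referenced to a CSF compartment, and the
  **phase-cancellation statistic**

  ```
  depth average = (1/D) Σ_d f(S_d)        # amplitudes first, phase lost
  ROI   average = f((1/D) Σ_d S_d)        # averaging first, phases interfere
  cancellation  = (depth avg − ROI avg) / depth avg
  ```

  where f is the fundamental-frequency Fourier amplitude of the trial
  mean. For pure sinusoids the ROI average is the magnitude of the mean
  phasor |Σ a_d e^{iφ_d}|/D, which the package also provides as a
  closed-form oracle.
- **Synthetic-session generator** — seeded NIfTI volumes with per-depth
  oscillation amplitudes and delays, CSF and control compartments, linear
  drift, white/AR(1) noise, and jittered dataglove traces, so every stage
  is testable without raw fMRI data.

## Worked example

```python
from boldwave import depth, hrf
import numpy as np

# canonical prediction: 0.5-Hz response relative to the 0.05-Hz reference
ratios = hrf.predicted_frequency_response((0.05, 0.5))
print(round(-np.log10(ratios[0.5]), 3))          # 3.016 -> ~1038x smaller

# two depths, equal amplitude, a quarter-cycle apart
res = depth.phasor_oracle([1.0, 1.0], [0.0, np.pi / 2])
print(round(res.cancellation, 4))                # 0.2929 = 1 - cos(pi/4)
```

The first number says the canonical HRF predicts a 0.5-Hz steady-state
oscillation about three orders of magnitude weaker than at 0.05 Hz; the
second is the amplitude fraction lost when two equally strong responses a
quarter cycle apart are averaged before the amplitude is taken.

## Analysis scripts

Numbered drivers under `analysis/` rebuild the study tables from scratch
and write them to `results/`:

| script | output | headline result |
|---|---|---|
| `01_predict_hrf_response.py` | `hrf_frequency_response.tsv` | prediction falls monotonically; −log10(ratio at 0.5 Hz) = 3.016 |
| `02_validate_kinematics.py` | `kinematics_performance.tsv` | 20/10/5/3/2 flexions per block from 0.05 to 0.5 Hz; pooled grasp rate within 2 ± 0.08 Hz |
| `03_run_synthetic_study.py` | `report.json` + TSV tables | measured normalized response ≫ prediction at high frequency; cancellation rises with frequency, ~10% in M1 vs ~6% in S1 at 0.5 Hz |
| `04_plot_figures.py` | `scratch/figures/*.png` | diagnostic plots of the above |

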
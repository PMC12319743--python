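"""ROI-level steady-state BOLD analysis.

Converts raw voxel series to percent signal change (linear detrend),
removes the initial transient by the closest-trial-to-65-s rule, computes
reference-normalized amplitude spectra and no-task noise floors, and folds
runs onto single-trial averages with across-voxel confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import amplitude_spectrum as _amp_spec


class InputError(ValueError):
    pass


@dataclass
class RoiTimeseries:
    """Percent-signal-change series for the voxels of one ROI."""

    data: np.ndarray  # (n_voxels, n_volumes)
    tr_s: float
    trial_onsets_s: np.ndarray
    roi_name: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.trial_onsets_s = np.asarray(self.trial_onsets_s, dtype=float)
        if len(self.trial_onsets_s) and np.any(np.diff(self.trial_onsets_s) <= 0):
            raise InputError("trial onsets must be strictly increasing")


@dataclass
class AmplitudeSpectrum:
    freq_hz: np.ndarray
    amplitude: np.ndarray        # % signal change, voxel-averaged magnitudes
    roi_name: str = ""
    normalized_to: str | None = None   # e.g. "M1 @ 0.05 Hz"
    reference_value: float | None = None

    def value_at(self, freq_hz: float) -> float:
        return float(self.amplitude[np.argmin(np.abs(self.freq_hz - freq_hz))])


@dataclass
class TrialAverage:
    """Mean single-trial response with a 95% CI across voxels."""

    time_s: np.ndarray
    mean: np.ndarray       # % signal change
    ci95: np.ndarray       # half-width per timepoint
    n_voxels: int
    n_runs: int
    voxel_means: np.ndarray = field(repr=False, default=None)


@dataclass
class NoiseFloor:
    freq_hz: np.ndarray
    single_run: np.ndarray
    scaled: dict[int, np.ndarray]  # run count -> floor


def percent_signal_change(raw: np.ndarray) -> np.ndarray:
    """Linear detrend per voxel, divide by the temporal mean, ×100, center.

    ``raw`` is (n_voxels, n_volumes) with positive mean; a constant or
    purely linear voxel maps to all zeros.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    mean = raw.mean(axis=-1)
    if np.any(mean <= 0):
        raise InputError("voxel temporal mean must be positive")
    n = raw.shape[-1]
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t - t.mean()])
    beta, *_ = np.linalg.lstsq(design, raw.T, rcond=None)
    resid = raw - (design @ beta).T
    pct = resid / mean[:, None] * 100.0
    return pct - pct.mean(axis=-1, keepdims=True)


def discard_transient(
    series: np.ndarray,
    tr_s: float,
    trial_onsets_s: np.ndarray,
    period_s: float,
    mark_s: float = 65.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Remove data before the trial onset closest to the 65-s mark.

    The retained record is truncated to an integer number of trial periods
    (trailing partial trial dropped).  When two onsets are equidistant from
    the mark the earlier one is kept (retains more data).

    Returns (truncated series, retained onsets, start volume index).
    """
    series = np.asarray(series, dtype=float)
    onsets = np.asarray(trial_onsets_s, dtype=float)
    n_t = series.shape[-1]
    i0 = int(np.argmin(np.abs(onsets - mark_s)))  # argmin takes the earlier on ties
    start = int(round(onsets[i0] / tr_s))
    per = int(round(period_s / tr_s))
    n_trials = (n_t - start) // per
    if n_trials < 2:
        raise InputError("fewer than 2 complete trials remain after the transient cut")
    end = start + n_trials * per
    return series[..., start:end], onsets[i0:i0 + n_trials], start


def amplitude_spectrum(roi_ts: RoiTimeseries, average: str = "magnitude") -> AmplitudeSpectrum:
    """Voxel-averaged one-sided amplitude spectrum of an ROI.

    Per-voxel spectra are averaged as magnitudes by default (an out-of-phase
    pair averages to its common amplitude, not zero); ``average="complex"``
    averages the complex spectra before taking magnitudes.
    """
    data = roi_ts.data
    n = data.shape[-1]
    freqs, amp = _amp_spec(data, roi_ts.tr_s)
    if average == "magnitude":
        mean_amp = amp.mean(axis=0)
    elif average == "complex":
        spec = np.fft.rfft(data, axis=-1).mean(axis=0)
        mean_amp = np.abs(spec) * 2.0 / n
        mean_amp[0] /= 2.0
        if n % 2 == 0:
            mean_amp[-1] /= 2.0
    else:
        raise ValueError("average must be 'magnitude' or 'complex'")
    return AmplitudeSpectrum(freq_hz=freqs, amplitude=mean_amp, roi_name=roi_ts.roi_name)


def normalize_spectrum(
    spec: AmplitudeSpectrum,
    reference: AmplitudeSpectrum,
    ref_freq_hz: float = 0.05,
) -> AmplitudeSpectrum:
    """Divide all amplitudes by the reference spectrum's 0.05-Hz fundamental.

    The M1 and control ROIs are normalized to the M1 reference run and the
    S1 ROI to the S1 reference run; the caller picks the reference spectrum
    accordingly.
    """
    ref_val = reference.value_at(ref_freq_hz)
    if ref_val == 0:
        raise InputError("reference spectrum has zero amplitude at the reference bin")
    return AmplitudeSpectrum(
        freq_hz=spec.freq_hz.copy(),
        amplitude=spec.amplitude / ref_val,
        roi_name=spec.roi_name,
        normalized_to=f"{reference.roi_name} @ {ref_freq_hz:g} Hz",
        reference_value=ref_val,
    )


def estimate_noise_floor(
    no_task_runs: list[RoiTimeseries],
    run_counts: tuple[int, ...] = (1, 2, 10),
) -> NoiseFloor:
    """Mean no-task amplitude spectrum and its √n-scaled multi-run floors.

    Each frequency bin of a task-free run is treated as an independent noise
    estimate; voxel (and run) spectra are averaged as magnitudes, and the
    floor for an n-run average is the single-run floor divided by √n.
    """
    if not no_task_runs:
        raise InputError("need at least one no-task run")
    specs = [amplitude_spectrum(r) for r in no_task_runs]
    freqs = specs[0].freq_hz
    single = np.mean([s.amplitude for s in specs], axis=0)
    scaled = {int(n): single / np.sqrt(n) for n in run_counts}
    return NoiseFloor(freq_hz=freqs, single_run=single, scaled=scaled)


def _partition(data: np.ndarray, tr_s: float, onsets_s: np.ndarray, per: int) -> np.ndarray:
    """Stack (n_voxels, n_trials, per) trial segments starting at each onset."""
    n_t = data.shape[-1]
    segs = []
    for onset in onsets_s:
        i = int(round(onset / tr_s))
        if i + per <= n_t:
            segs.append(data[:, i:i + per])
    if len(segs) < 2:
        raise InputError("need at least 2 complete trials")
    return np.stack(segs, axis=1)


def trial_average(
    runs: RoiTimeseries | list[RoiTimeseries],
    period_s: float,
) -> TrialAverage:
    """Fold runs onto one trial period and average voxel by voxel.

    The mean trial response is computed per voxel per run, then averaged
    across runs, then across voxels; the 95% CI half-width per timepoint is
    1.96 × SD(voxel-level trial means)/√n_voxels.  Trial boundaries come
    from each run's ``trial_onsets_s`` (detected motion onsets when a glove
    trace was supplied, nominal paradigm onsets otherwise).
    """
    if isinstance(runs, RoiTimeseries):
        runs = [runs]
    per = int(round(period_s / runs[0].tr_s))
    if abs(per * runs[0].tr_s - period_s) > 1e-9:
        raise InputError("trial period must be an integer number of TRs")
    voxel_run_means = []
    for r in runs:
        trials = _partition(r.data, r.tr_s, r.trial_onsets_s, per)
        voxel_run_means.append(trials.mean(axis=1))  # (n_vox, per)
    voxel_means = np.mean(voxel_run_means, axis=0)
    mean = voxel_means.mean(axis=0)
    n_vox = voxel_means.shape[0]
    if n_vox > 1:
        ci95 = 1.96 * voxel_means.std(axis=0, ddof=1) / np.sqrt(n_vox)
    else:
        ci95 = np.zeros_like(mean)
    return TrialAverage(
        time_s=np.arange(per) * runs[0].tr_s,
        mean=mean, ci95=ci95, n_voxels=n_vox, n_runs=len(runs),
        voxel_means=voxel_means,
    )


def peak_to_peak(ta: TrialAverage) -> float:
    """Max − min of the mean trial response (% signal change)."""
    return float(np.max(ta.mean) - np.min(ta.mean))
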
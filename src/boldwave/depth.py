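"""Cortical-depth-resolved amplitude, delay and phase-cancellation analysis.

Per-depth trial-averaged responses S_d are fitted with a sinusoid at the
stimulus frequency to obtain amplitude and phase (hence delay, referenced to
a CSF compartment).  Averaging responses across depths *before* taking the
amplitude lets out-of-phase depths interfere destructively; the cancellation
statistic quantifies the resulting amplitude loss:

    depth-average signal change = (1/D) Σ_d f(S_d)
    ROI-average   signal change = f((1/D) Σ_d S_d)
    cancellation = (depth-average − ROI-average) / depth-average

where f is the amplitude operator (fundamental-frequency Fourier amplitude
of the trial mean by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import fourier_upsample, fundamental_amplitude
from .steady_state import InputError, RoiTimeseries, TrialAverage, trial_average


@dataclass
class DepthTrialSet:
    """Trial-averaged responses S_d for the D depth bins of one ROI."""

    time_s: np.ndarray
    responses: np.ndarray       # (D, n_timepoints); NaN rows for empty bins
    n_voxels: np.ndarray        # voxel count per bin
    stim_freq_hz: float
    roi_name: str = ""
    f_convention: str = "fundamental"  # amplitude operator tag

    @property
    def n_depths(self) -> int:
        return self.responses.shape[0]

    @property
    def occupied(self) -> np.ndarray:
        return self.n_voxels > 0


@dataclass
class SineFit:
    """Least-squares sinusoid fit a + b·sin(2πft) + c·cos(2πft)."""

    amplitude: float
    phase: float        # rad in (−π, π]; positive phase = later response
    offset: float
    rss: float
    stim_freq_hz: float
    degenerate: bool = False

    @property
    def delay_s(self) -> float:
        return self.phase / (2.0 * np.pi * self.stim_freq_hz)


@dataclass
class DelayProfile:
    delay_s: np.ndarray          # per depth, relative to CSF
    phase_rad: np.ndarray        # per depth, relative to CSF (unwrapped)
    csf_reference_delay_s: float


@dataclass
class CancellationResult:
    depth_average_signal_change: float
    roi_average_signal_change: float
    cancellation: float
    degenerate: bool = False


def depth_trial_set(
    data_pct,
    depth_labels: np.ndarray,
    n_bins: int,
    tr_s: float,
    trial_onsets_s,
    period_s: float,
    stim_freq_hz: float,
    roi_name: str = "",
) -> DepthTrialSet:
    """Per-depth trial averages for one ROI.

    ``data_pct`` is (n_voxels, n_volumes) percent signal change — or a list
    of such arrays, one per run, with ``trial_onsets_s`` a matching list —
    and ``depth_labels`` the per-voxel depth bin in [0, n_bins).  Averaging
    follows the voxel-then-run order of the ROI-level trial average.  Empty
    bins are reported with zero voxels (NaN response) and a warning, never
    silently dropped.
    """
    if not isinstance(data_pct, (list, tuple)):
        data_pct = [data_pct]
        trial_onsets_s = [trial_onsets_s]
    data_pct = [np.atleast_2d(r) for r in data_pct]
    depth_labels = np.asarray(depth_labels)
    if depth_labels.min(initial=0) < 0 or depth_labels.max(initial=0) >= n_bins:
        raise InputError("depth labels must lie in [0, n_bins)")
    per = int(round(period_s / tr_s))
    responses = np.full((n_bins, per), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    time_s = np.arange(per) * tr_s
    for d in range(n_bins):
        m = depth_labels == d
        counts[d] = int(m.sum())
        if counts[d] == 0:
            warnings.warn(f"depth bin {d} of {roi_name or 'ROI'} is empty")
            continue
        runs = [
            RoiTimeseries(r[m], tr_s, ons, roi_name=f"{roi_name}:d{d}")
            for r, ons in zip(data_pct, trial_onsets_s)
        ]
        ta = trial_average(runs, period_s)
        responses[d] = ta.mean
        time_s = ta.time_s
    return DepthTrialSet(
        time_s=time_s, responses=responses, n_voxels=counts,
        stim_freq_hz=stim_freq_hz, roi_name=roi_name,
    )


def upsample_trial(trial_mean: np.ndarray, factor: int = 50) -> np.ndarray:
    """Band-limited periodic interpolation of a trial mean (10-ms steps for
    a TR-0.5-s trial at the default factor).  Original samples preserved."""
    trial_mean = np.asarray(trial_mean, dtype=float)
    if trial_mean.shape[-1] < 3:
        raise InputError("need at least 3 samples per trial")
    return fourier_upsample(trial_mean, factor)


def fit_sine(
    trial_mean: np.ndarray, time_s: np.ndarray, stim_freq_hz: float
) -> SineFit:
    """Least-squares sinusoid at the stimulus frequency.

    Solves y = a + b·sin(2πft) + c·cos(2πft); amplitude = √(b²+c²).  The
    phase is reported with the sign convention that a response delayed by τ
    has phase 2πfτ (positive = later), so delay_s = phase/(2πf).  A constant
    input yields amplitude 0 with the degenerate flag set, not an exception.
    """
    y = np.asarray(trial_mean, dtype=float)
    t = np.asarray(time_s, dtype=float)
    period = 1.0 / stim_freq_hz
    if len(y) < 3 or (t[1] - t[0]) > period / 3.0 + 1e-12:
        raise InputError("need at least 3 samples per stimulus period")
    w = 2.0 * np.pi * stim_freq_hz * t
    design = np.column_stack([np.ones_like(t), np.sin(w), np.cos(w)])
    (a, b, c), res, *_ = np.linalg.lstsq(design, y, rcond=None)
    amp = float(np.hypot(b, c))
    fitted = design @ [a, b, c]
    rss = float(np.sum((y - fitted) ** 2))
    scale = max(np.max(np.abs(y)), 1.0e-300)
    if amp <= 1e-12 * scale:
        return SineFit(0.0, np.nan, float(a), rss, stim_freq_hz, degenerate=True)
    # y = a + amp·sin(2πft + φ0) with φ0 = atan2(c, b); delay phase = −φ0
    phase = float(-np.arctan2(c, b))
    phase = (phase + np.pi) % (2.0 * np.pi) - np.pi
    if phase <= -np.pi:
        phase += 2.0 * np.pi
    return SineFit(amp, phase, float(a), rss, stim_freq_hz)


def delay_profile(
    depth_fits: list[SineFit],
    csf_fit: SineFit,
    stim_freq_hz: float,
) -> DelayProfile:
    """Per-depth delays relative to the CSF reference.

    Phases are unwrapped marching from the CSF reference (adjacent to the
    pial surface, the last depth index) inward toward the white matter, so
    adjacent-depth phase jumps exceed π only if the data truly demand it.
    Relevant mainly at 0.5 Hz where delays approach half a period.
    """
    if csf_fit.degenerate:
        raise InputError("degenerate CSF reference fit")
    phases = np.array([f.phase for f in depth_fits], dtype=float)
    # sequence ordered CSF -> pial -> ... -> white matter
    seq = np.r_[csf_fit.phase, phases[::-1]]
    seq = np.unwrap(seq)
    rel = (seq[1:] - seq[0])[::-1]
    delays = rel / (2.0 * np.pi * stim_freq_hz)
    return DelayProfile(
        delay_s=delays, phase_rad=rel,
        csf_reference_delay_s=csf_fit.delay_s,
    )


def _amplitude_operator(
    x: np.ndarray, time_s: np.ndarray, stim_freq_hz: float,
    convention: str, upsample_factor: int,
) -> float:
    if convention == "fundamental":
        # interpolation-invariant at the fundamental; apply to the raw mean
        dt = time_s[1] - time_s[0]
        return fundamental_amplitude(x, dt, stim_freq_hz)
    if convention == "ptp":
        dense = upsample_trial(x, upsample_factor)
        return float((dense.max() - dense.min()) / 2.0)
    raise ValueError("f_convention must be 'fundamental' or 'ptp'")


def cancellation(
    depth_set: DepthTrialSet,
    f_convention: str | None = None,
    upsample_factor: int = 50,
) -> CancellationResult:
    """Phase-cancellation statistic across the depth bins of one ROI.

    f(S_d) is the fundamental-frequency Fourier amplitude of the trial mean
    (``f_convention="ptp"`` switches to half the upsampled peak-to-peak for
    sensitivity analysis).  Empty bins are excluded from both averages.
    A zero depth-average makes the statistic undefined (degenerate flag).
    """
    conv = f_convention or depth_set.f_convention
    occ = depth_set.occupied
    if occ.sum() < 2:
        raise InputError("need at least 2 occupied depth bins")
    S = depth_set.responses[occ]
    t = depth_set.time_s
    f = depth_set.stim_freq_hz
    amps = [_amplitude_operator(s, t, f, conv, upsample_factor) for s in S]
    depth_avg = float(np.mean(amps))
    roi_avg = _amplitude_operator(S.mean(axis=0), t, f, conv, upsample_factor)
    if depth_avg == 0.0:
        return CancellationResult(depth_avg, roi_avg, np.nan, degenerate=True)
    return CancellationResult(depth_avg, float(roi_avg), (depth_avg - roi_avg) / depth_avg)


def phasor_oracle(amplitudes, phases) -> CancellationResult:
    """Closed-form cancellation for pure sinusoids at a common frequency.

    With S_d = a_d sin(2πft + φ_d): the depth average is mean(a_d) and the
    ROI average is |Σ a_d e^{iφ_d}|/D — the magnitude of the mean phasor.
    Serves as the independent oracle for :func:`cancellation`.
    """
    a = np.asarray(amplitudes, dtype=float)
    phi = np.asarray(phases, dtype=float)
    depth_avg = float(np.mean(a))
    roi_avg = float(np.abs(np.sum(a * np.exp(1j * phi))) / len(a))
    if depth_avg == 0.0:
        return CancellationResult(depth_avg, roi_avg, np.nan, degenerate=True)
    return CancellationResult(depth_avg, roi_avg, (depth_avg - roi_avg) / depth_avg)
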
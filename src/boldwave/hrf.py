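"""Canonical double-gamma HRF predictions of steady-state BOLD responses.

The canonical hemodynamic response function is the difference of two gamma
densities — a positive lobe peaking near 5 s and a later undershoot scaled
down by a fixed ratio.  Convolving a block-paradigm boxcar with this kernel
predicts the steady-state BOLD oscillation evoked at each stimulus
frequency; because the kernel acts as a low-pass filter, predicted
fundamental amplitudes fall steeply with frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral import fundamental_amplitude


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma kernel parameters (defaults: the standard canonical set).

    Delays and dispersions are in seconds; ``peak_to_undershoot_ratio``
    divides the undershoot gamma.  ``dt_s`` is the microtime step the kernel
    is sampled on (default TR/16 for TR = 0.5 s).
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_to_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0
    dt_s: float = 0.03125

    def __post_init__(self):
        vals = (self.peak_delay_s, self.undershoot_delay_s, self.peak_dispersion,
                self.undershoot_dispersion, self.peak_to_undershoot_ratio,
                self.kernel_length_s, self.dt_s)
        if any(v <= 0 for v in vals):
            raise ConfigurationError("all HRF parameters must be positive")
        if self.kernel_length_s < self.undershoot_delay_s + 3 * self.undershoot_dispersion:
            raise ConfigurationError("kernel too short to contain the undershoot")


@dataclass
class PredictedTimecourse:
    """Boxcar regressor plus its HRF-convolved response on the TR grid."""

    regressor: np.ndarray  # microtime grid
    response: np.ndarray   # TR grid
    tr_s: float


def canonical_hrf(params: HRFParams | None = None) -> np.ndarray:
    """Sampled double-gamma kernel, scaled to unit peak.

    h(t) = Gamma(t; peak) − Gamma(t; undershoot)/ratio, with gamma shapes
    delay/dispersion and scales equal to the dispersions.  Unit-peak scaling
    is immaterial for the ratio-based predictions reported downstream.
    """
    p = params or HRFParams()
    t = np.arange(0.0, p.kernel_length_s, p.dt_s)
    peak = stats.gamma.pdf(t, a=p.peak_delay_s / p.peak_dispersion,
                           scale=p.peak_dispersion)
    under = stats.gamma.pdf(t, a=p.undershoot_delay_s / p.undershoot_dispersion,
                            scale=p.undershoot_dispersion)
    h = peak - under / p.peak_to_undershoot_ratio
    return h / h.max()


def transfer_magnitude(kernel: np.ndarray, freq_hz: float, dt_s: float) -> float:
    """|H(f)| of the sampled kernel: magnitude of Σ h_m e^{−2πi f m dt}.

    Dimensionless (no dt factor), matching discrete convolution of sampled
    series, so the steady-state output amplitude of a unit-amplitude input
    sinusoid at f is exactly |H(f)|.
    """
    m = np.arange(len(kernel))
    return float(np.abs(np.sum(kernel * np.exp(-2j * np.pi * freq_hz * m * dt_s))))


def predict_response(
    regressor: np.ndarray, kernel: np.ndarray, tr_s: float, dt_s: float
) -> PredictedTimecourse:
    """Convolve a microtime regressor with the kernel; resample to the TR grid.

    Linear convolution truncated to the run length; the TR-grid response
    takes the microtime sample at each volume onset.
    """
    regressor = np.asarray(regressor, dtype=float)
    if len(kernel) > len(regressor):
        raise ValueError("kernel longer than the run")
    step = int(round(tr_s / dt_s))
    if abs(step * dt_s - tr_s) > 1e-9:
        raise ValueError("tr_s must be an integer multiple of dt_s")
    micro = np.convolve(regressor, kernel)[: len(regressor)]
    response = micro[::step]
    return PredictedTimecourse(regressor=regressor, response=response, tr_s=tr_s)


def predicted_frequency_response(
    freqs_hz=(0.05, 0.10, 0.20, 1.0 / 3.0, 0.50),
    tr_s: float = 0.5,
    n_volumes: int = 480,
    lead_in_off_s: float = 0.0,
    params: HRFParams | None = None,
    regressors: dict | None = None,
    ref_freq_hz: float = 0.05,
) -> dict[float, float]:
    """Predicted steady-state fundamental amplitudes, normalized to 0.05 Hz.

    For each frequency: build the paradigm boxcar on the microtime grid (or
    take a supplied regressor, e.g. one derived from recorded hand motion),
    convolve with the canonical kernel, discard the pre-65-s transient by
    the closest-trial rule, and measure the fundamental amplitude.  Values
    are ratios to the reference-frequency amplitude.
    """
    from .steady_state import discard_transient
    from .synth import make_paradigm

    p = params or HRFParams(dt_s=tr_s / 16.0)
    kernel = canonical_hrf(p)

    def amp(freq):
        paradigm = make_paradigm(freq, tr_s=tr_s, n_volumes=n_volumes,
                                 lead_in_off_s=lead_in_off_s)
        if regressors is not None and freq in regressors:
            reg = np.asarray(regressors[freq], dtype=float)
        else:
            reg = paradigm.boxcar(dt=p.dt_s)
        tc = predict_response(reg, kernel, tr_s, p.dt_s)
        ss, _, _ = discard_transient(tc.response, tr_s,
                                     paradigm.trial_onsets_s, paradigm.period_s)
        return fundamental_amplitude(ss, tr_s, paradigm.stim_freq_hz)

    ref = amp(ref_freq_hz)
    return {float(f): amp(f) / ref for f in freqs_hz}
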
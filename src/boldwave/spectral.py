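"""Shared spectral utilities.

Amplitude convention used throughout the package: the one-sided amplitude
spectrum is scaled so that the value in bin f equals the *peak* amplitude of
a sinusoid at frequency f.  For a record of N uniformly spaced samples this
is 2|X_k|/N for 0 < k < N/2, |X_0|/N at DC and |X_{N/2}|/N at Nyquist.
Records produced by the steady-state pipeline contain an integer number of
stimulus periods, so the stimulus fundamental falls on an exact FFT bin and
the rectangular window introduces no leakage there.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def amplitude_spectrum(x: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum with sinusoid-peak calibration.

    Parameters
    ----------
    x : array, shape (..., n)
        Real time series along the last axis.
    dt : float
        Sample spacing in seconds.

    Returns
    -------
    freqs : array, shape (n//2 + 1,)
        Frequency grid in Hz.
    amp : array, shape (..., n//2 + 1)
        Peak-amplitude-calibrated spectrum (same units as ``x``).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    amp = np.abs(np.fft.rfft(x, axis=-1)) * (2.0 / n)
    amp[..., 0] /= 2.0
    if n % 2 == 0:
        amp[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, dt)
    return freqs, amp


def fundamental_bin(n: int, dt: float, freq_hz: float) -> int:
    """Index of the FFT bin closest to ``freq_hz`` for an n-sample record."""
    freqs = np.fft.rfftfreq(n, dt)
    return int(np.argmin(np.abs(freqs - freq_hz)))


def fundamental_amplitude(x: np.ndarray, dt: float, freq_hz: float) -> float:
    """Peak amplitude of the sinusoidal component at ``freq_hz``.

    Reads the amplitude spectrum at the bin nearest the requested frequency;
    exact when the record holds an integer number of periods.
    """
    x = np.asarray(x, dtype=float)
    freqs, amp = amplitude_spectrum(x, dt)
    k = int(np.argmin(np.abs(freqs - freq_hz)))
    return float(amp[..., k]) if x.ndim == 1 else amp[..., k]


def fourier_upsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Band-limited (zero-padded spectrum) periodic interpolation.

    Original samples are preserved at indices ``k * factor``.  Suitable for
    trial-averaged responses, which are periodic by construction.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("upsampling factor must be a positive integer")
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    return signal.resample(x, x.shape[-1] * int(factor), axis=-1)
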
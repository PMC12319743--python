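"""Hand-motion detection from dataglove joint-angle traces.

Motion on-blocks are found by thresholding the smoothed first-order
derivative of the joint angle (Savitzky–Golay filter); flexions are counted
as positive-going derivative threshold crossings with hysteresis; the grasp
frequency is the flexion count divided by the detected on-block duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synth import GloveTrace, ParadigmSpec


class EstimationError(RuntimeError):
    """Raised when no usable motion blocks are available for an estimate."""


@dataclass
class MotionEvents:
    """Detected motion blocks and flexion statistics for one run."""

    block_onsets_s: np.ndarray
    block_offsets_s: np.ndarray
    flexions_per_block: np.ndarray
    grasp_freq_hz_per_block: np.ndarray
    grasp_freq_hz: float  # pooled, duration-weighted

    def __post_init__(self):
        on, off = self.block_onsets_s, self.block_offsets_s
        if len(on) != len(off):
            raise ValueError("onset/offset length mismatch")
        if len(on) and (np.any(off <= on) or np.any(np.diff(on) <= 0)
                        or np.any(on[1:] < off[:-1])):
            raise ValueError("blocks must be sorted and non-overlapping")

    @property
    def n_blocks(self) -> int:
        return len(self.block_onsets_s)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "onset_s": self.block_onsets_s,
            "offset_s": self.block_offsets_s,
            "n_flexions": self.flexions_per_block,
            "grasp_freq_hz": self.grasp_freq_hz_per_block,
        }).to_csv(path, sep="\t", index=False, float_format="%.6f")


def sg_derivative(trace: GloveTrace, window: int = 7, polyorder: int = 3) -> np.ndarray:
    """Savitzky–Golay smoothed first derivative of the joint angle (deg/s)."""
    if window % 2 == 0 or window <= polyorder or polyorder < 1:
        raise ValueError("window must be odd and > polyorder >= 1")
    if len(trace.angle_deg) < window:
        raise ValueError("trace shorter than the filter window")
    dt = 1.0 / trace.fs_hz
    return savgol_filter(trace.angle_deg, window, polyorder, deriv=1, delta=dt)


def detect_blocks(
    deriv: np.ndarray,
    fs_hz: float,
    threshold_frac: float = 0.2,
    min_gap_s: float = 0.25,
    min_duration_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Intervals where |derivative| exceeds a fraction of its maximum.

    Sub-threshold gaps shorter than ``min_gap_s`` are merged (a 2-Hz flexion
    cycle's zero crossings must not split a block) and intervals shorter than
    ``min_duration_s`` (one flexion period by default) are discarded.
    An all-zero derivative yields zero blocks.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must be in (0, 1)")
    deriv = np.asarray(deriv, dtype=float)
    peak = np.max(np.abs(deriv))
    if peak == 0.0:
        return []
    above = np.abs(deriv) > threshold_frac * peak
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.r_[idx[0], idx[splits + 1]]
    run_ends = np.r_[idx[splits], idx[-1]] + 1  # half-open sample ranges

    # merge runs separated by gaps shorter than min_gap_s
    merged = [[run_starts[0], run_ends[0]]]
    max_gap = int(round(min_gap_s * fs_hz))
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        if (e - s) / fs_hz >= min_duration_s:
            out.append((s / fs_hz, e / fs_hz))
    return out


def count_flexions(
    trace: GloveTrace,
    blocks: list[tuple[float, float]],
    threshold_frac: float = 0.2,
    window: int = 7,
    polyorder: int = 3,
) -> np.ndarray:
    """Flexions per block: positive-going derivative crossings with hysteresis.

    A flexion is counted when the derivative rises above ``+threshold_frac ×
    max|derivative|``; the counter re-arms only after the derivative falls
    below the mirrored lower threshold, so noisy crossings are not counted
    twice.  One count per flexion cycle.
    """
    deriv = sg_derivative(trace, window=window, polyorder=polyorder)
    peak = np.max(np.abs(deriv))
    counts = np.zeros(len(blocks), dtype=int)
    if peak == 0.0:
        return counts
    upper, lower = threshold_frac * peak, -threshold_frac * peak
    for i, (on, off) in enumerate(blocks):
        d = deriv[(trace.time_s >= on) & (trace.time_s < off)]
        armed, n = True, 0
        for v in d:
            if armed and v > upper:
                n += 1
                armed = False
            elif not armed and v < lower:
                armed = True
        counts[i] = n
    return counts


def estimate_grasp_frequency(
    blocks: list[tuple[float, float]], counts: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-block and pooled grasp frequency (flexions / on-block duration).

    The pooled value is the duration-weighted mean of the per-block rates,
    i.e. total flexions over total detected on-block time.
    """
    counts = np.asarray(counts)
    if len(blocks) == 0 or counts.max(initial=0) < 1:
        raise EstimationError("no motion blocks with at least one flexion")
    durations = np.array([off - on for on, off in blocks])
    per_block = counts / durations
    pooled = float(counts.sum() / durations.sum())
    return per_block, pooled


def detect_motion(
    trace: GloveTrace,
    threshold_frac: float = 0.2,
    min_gap_s: float = 0.25,
    min_duration_s: float = 0.5,
    window: int = 7,
    polyorder: int = 3,
) -> MotionEvents:
    """Full kinematic analysis of one glove trace."""
    deriv = sg_derivative(trace, window=window, polyorder=polyorder)
    blocks = detect_blocks(deriv, trace.fs_hz, threshold_frac, min_gap_s,
                           min_duration_s)
    counts = count_flexions(trace, blocks, threshold_frac, window, polyorder)
    if len(blocks) and counts.max(initial=0) >= 1:
        per_block, pooled = estimate_grasp_frequency(blocks, counts)
    else:
        per_block, pooled = np.zeros(len(blocks)), float("nan")
    return MotionEvents(
        block_onsets_s=np.array([b[0] for b in blocks]),
        block_offsets_s=np.array([b[1] for b in blocks]),
        flexions_per_block=counts,
        grasp_freq_hz_per_block=per_block,
        grasp_freq_hz=pooled,
    )


def motion_regressor(
    events: MotionEvents, tr_s: float, n_volumes: int
) -> np.ndarray:
    """Volume-gridded boxcar from detected motion blocks.

    A volume is 1 when detected motion covers at least 50% of its TR
    interval.
    """
    reg = np.zeros(n_volumes)
    t0 = np.arange(n_volumes) * tr_s
    t1 = t0 + tr_s
    for on, off in zip(events.block_onsets_s, events.block_offsets_s):
        overlap = np.minimum(t1, off) - np.maximum(t0, on)
        reg[overlap >= 0.5 * tr_s] = 1.0
    return reg


def nominal_events(paradigm: ParadigmSpec) -> MotionEvents:
    """MotionEvents matching the nominal paradigm timing exactly."""
    onsets = paradigm.trial_onsets_s
    offsets = onsets + paradigm.on_s
    n = int(round(paradigm.on_s * paradigm.flexion_rate_hz))
    counts = np.full(len(onsets), n)
    per_block, pooled = estimate_grasp_frequency(
        list(zip(onsets, offsets)), counts
    )
    return MotionEvents(onsets, offsets, counts, per_block, pooled)
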
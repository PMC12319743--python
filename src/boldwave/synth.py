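"""Synthetic laminar fMRI sessions with steady-state oscillating BOLD signals.

Emulates the study conditions the analysis modules assume: block paradigms at
0.05/0.10/0.20/0.33/0.50 Hz with equal on/off blocks, TR = 0.5 s runs of 480
volumes (520 with a 20-s lead-in off block), depth-resolved oscillation
amplitudes and delays in two cortical ROIs (7 depth bins in S1, 15 in M1),
CSF and control compartments, linear drift with white/AR(1) noise, and a
15-Hz dataglove trace with 2-Hz finger flexion during on-blocks.

The generator is fully seeded: a session is a pure function of its three
specs plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import signal as _signal

from . import hrf as _hrf
from .spectral import fundamental_amplitude

#: Stimulus frequencies used in the study, as exact trial periods in seconds.
SUPPORTED_PERIODS_S = (20.0, 10.0, 5.0, 3.0, 2.0)
SUPPORTED_FREQS_HZ = tuple(1.0 / p for p in SUPPORTED_PERIODS_S)

GLOVE_FS_HZ = 15.0
BASELINE_SIGNAL = 1000.0  # arbitrary units; keeps % signal change well-conditioned

#: Integer codes used in the ROI label volume.
ROI_CODES = {
    "background": 0,
    "M1": 1,
    "S1": 2,
    "control1": 3,
    "control2": 4,
    "CSF": 5,
}
ROI_NAMES = {v: k for k, v in ROI_CODES.items()}


class ConfigurationError(ValueError):
    """Raised when a paradigm or session spec is internally inconsistent."""


# --------------------------------------------------------------------------
# paradigm
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParadigmSpec:
    """Block-paradigm timing: equal on/off blocks at one stimulus frequency.

    ``stim_freq_hz`` is the trial (on+off) repetition rate; on- and off-block
    durations are both half a trial period.  ``lead_in_off_s`` models the
    optional 20-s rest block prepended to a run; the first on-block starts at
    t = lead_in_off_s.  Dummy scans are never represented: t = 0 is the first
    retained volume.
    """

    stim_freq_hz: float
    on_s: float
    off_s: float
    tr_s: float = 0.5
    n_volumes: int = 480
    lead_in_off_s: float = 0.0
    flexion_rate_hz: float = 2.0

    def __post_init__(self):
        if abs(self.on_s - self.off_s) > 1e-9:
            raise ConfigurationError("on/off blocks must have equal duration")
        if abs(self.stim_freq_hz * (self.on_s + self.off_s) - 1.0) > 1e-9:
            raise ConfigurationError("stim_freq_hz must equal 1/(on_s + off_s)")
        min_s = self.lead_in_off_s + 65.0 + 2.0 * self.period_s
        if self.n_volumes * self.tr_s < min_s:
            raise ConfigurationError(
                f"run too short: {self.n_volumes * self.tr_s:.1f} s < "
                f"{min_s:.1f} s needed for steady-state analysis"
            )

    @property
    def period_s(self) -> float:
        return self.on_s + self.off_s

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def trial_onsets_s(self) -> np.ndarray:
        """Nominal on-block onsets of all complete trials in the run."""
        n = int(np.floor((self.duration_s - self.lead_in_off_s) / self.period_s + 1e-9))
        return self.lead_in_off_s + np.arange(n) * self.period_s

    def boxcar(self, dt: float | None = None) -> np.ndarray:
        """Stimulus boxcar sampled at ``dt`` (default: the TR grid).

        1 during on-blocks, 0 otherwise; half-open on-intervals so a sample
        exactly at an on→off boundary is off.
        """
        dt = self.tr_s if dt is None else dt
        n = int(round(self.duration_s / dt))
        t = np.arange(n) * dt
        phase = np.mod(t - self.lead_in_off_s, self.period_s)
        box = ((t >= self.lead_in_off_s - 1e-9) & (phase < self.on_s - 1e-9)).astype(float)
        return box


def make_paradigm(
    freq_hz: float,
    tr_s: float = 0.5,
    n_volumes: int = 480,
    lead_in_off_s: float = 0.0,
    flexion_rate_hz: float = 2.0,
) -> ParadigmSpec:
    """Build a ParadigmSpec for one of the supported stimulus frequencies.

    The frequency is snapped to the exact rational period (e.g. 0.33 Hz is
    represented by a 3-s trial), so every trial spans an integer number of
    TRs for the TRs used in the study.
    """
    periods = np.asarray(SUPPORTED_PERIODS_S)
    match = np.isclose(1.0 / periods, freq_hz, rtol=0.02)
    if not match.any():
        raise ConfigurationError(
            f"unsupported stimulus frequency {freq_hz} Hz; "
            f"supported: {[round(f, 3) for f in SUPPORTED_FREQS_HZ]}"
        )
    period = float(periods[match][0])
    return ParadigmSpec(
        stim_freq_hz=1.0 / period,
        on_s=period / 2.0,
        off_s=period / 2.0,
        tr_s=tr_s,
        n_volumes=n_volumes,
        lead_in_off_s=lead_in_off_s,
        flexion_rate_hz=flexion_rate_hz,
    )


# --------------------------------------------------------------------------
# dataglove
# --------------------------------------------------------------------------

@dataclass
class GloveTrace:
    """Single-channel joint-angle recording on a uniform 15-Hz grid.

    ``angle_deg`` summarizes the proximal interphalangeal joint angle;
    an increase means flexion.  ``trigger_s`` holds scanner trigger times
    (one per volume).
    """

    time_s: np.ndarray
    angle_deg: np.ndarray
    trigger_s: np.ndarray

    def __post_init__(self):
        d = np.diff(self.time_s)
        if len(d) and (d.min() <= 0 or np.ptp(d) > 1e-6):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def to_tsv(self, path: str | Path) -> None:
        trig = np.zeros_like(self.time_s)
        idx = np.searchsorted(self.time_s, self.trigger_s)
        trig[np.clip(idx, 0, len(trig) - 1)] = 1.0
        pd.DataFrame(
            {"time_s": self.time_s, "angle_deg": self.angle_deg, "trigger": trig}
        ).to_csv(path, sep="\t", index=False, float_format="%.9f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GloveTrace":
        df = pd.read_csv(path, sep="\t")
        t = df["time_s"].to_numpy(float)
        return cls(
            time_s=t,
            angle_deg=df["angle_deg"].to_numpy(float),
            trigger_s=t[df["trigger"].to_numpy(float) > 0.5],
        )


def simulate_glove(
    paradigm: ParadigmSpec,
    jitter_sd_s: float = 0.0,
    seed: int = 0,
    amplitude_deg: float = 45.0,
    baseline_deg: float = 5.0,
) -> GloveTrace:
    """Simulate a dataglove trace: 2-Hz flexion during on-blocks, rest otherwise.

    Each on-block contains ``on_s * flexion_rate_hz`` raised-cosine flexion
    cycles, so the angle leaves and returns to baseline smoothly.  Block
    boundaries are perturbed by independent Gaussian jitter of SD
    ``jitter_sd_s`` (the paced flexion cycles stretch to fill the jittered
    block), emulating imperfect task execution.
    """
    if jitter_sd_s < 0:
        raise ConfigurationError("jitter_sd_s must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(np.floor(paradigm.duration_s * GLOVE_FS_HZ))
    t = np.arange(n) / GLOVE_FS_HZ
    angle = np.full(n, baseline_deg, dtype=float)

    n_cycles = int(round(paradigm.on_s * paradigm.flexion_rate_hz))
    for onset in paradigm.trial_onsets_s:
        on0 = onset + rng.normal(0.0, jitter_sd_s)
        on1 = onset + paradigm.on_s + rng.normal(0.0, jitter_sd_s)
        if on1 <= on0:  # degenerate jitter draw: skip the block
            continue
        m = (t >= on0) & (t < on1)
        u = (t[m] - on0) / (on1 - on0)  # 0..1 across the block
        angle[m] += 0.5 * amplitude_deg * (1.0 - np.cos(2.0 * np.pi * n_cycles * u))

    triggers = np.arange(paradigm.n_volumes) * paradigm.tr_s
    return GloveTrace(time_s=t, angle_deg=angle, trigger_s=triggers)


# --------------------------------------------------------------------------
# depth-resolved signal model
# --------------------------------------------------------------------------

#: Default normalized response amplitude vs stimulus frequency (relative to
#: 0.05 Hz).  Chosen to emulate a measured steady-state frequency response in
#: which the amplitude falls about twentyfold between 0.05 and 0.5 Hz while
#: remaining far above canonical-HRF predictions.
DEFAULT_FREQ_SCALE = {
    0.05: 1.00,
    0.10: 0.60,
    0.20: 0.25,
    1.0 / 3.0: 0.12,
    0.50: 0.05,
}


def _freq_scale(table: dict[float, float], freq_hz: float) -> float:
    for f, s in table.items():
        if np.isclose(f, freq_hz, rtol=0.02):
            return float(s)
    raise ConfigurationError(f"no amplitude scale defined for {freq_hz} Hz")


@dataclass(frozen=True)
class DepthSignalSpec:
    """Ground-truth oscillation amplitude and delay per cortical depth.

    Depth index 0 is the white-matter interface, the maximum index the pial
    surface.  ``amplitude_pct`` values are fundamental amplitudes in percent
    signal change at the 0.05-Hz reference; they are scaled by ``freq_scale``
    at other stimulus frequencies.  CSF is a separate compartment, not a
    depth bin.
    """

    n_depths_s1: int = 7
    n_depths_m1: int = 15
    amplitude_pct_m1: tuple = ()
    amplitude_pct_s1: tuple = ()
    delay_s_m1: tuple = ()
    delay_s_s1: tuple = ()
    csf_amplitude_pct: float = 4.0
    csf_delay_s: float = 0.55
    voxels_per_depth: int = 12
    waveform: str = "sinusoid"  # or "hrf_boxcar"
    freq_scale: tuple = tuple(sorted(DEFAULT_FREQ_SCALE.items()))

    def __post_init__(self):
        if self.n_depths_s1 < 2 or self.n_depths_m1 < 2:
            raise ConfigurationError("need at least 2 depth bins per ROI")
        if self.waveform not in ("sinusoid", "hrf_boxcar"):
            raise ConfigurationError(f"unknown waveform {self.waveform!r}")
        for name, default in (
            ("amplitude_pct_m1", self._linear(1.0, 3.0, self.n_depths_m1)),
            ("amplitude_pct_s1", self._linear(1.2, 3.5, self.n_depths_s1)),
            ("delay_s_m1", self._linear(0.0, 0.5, self.n_depths_m1)),
            ("delay_s_s1", self._linear(0.0, 0.35, self.n_depths_s1)),
        ):
            val = getattr(self, name)
            if len(val) == 0:
                object.__setattr__(self, name, default)
        n_m1 = len(self.amplitude_pct_m1)
        n_s1 = len(self.amplitude_pct_s1)
        if n_m1 != self.n_depths_m1 or len(self.delay_s_m1) != self.n_depths_m1:
            raise ConfigurationError("M1 amplitude/delay length must match n_depths_m1")
        if n_s1 != self.n_depths_s1 or len(self.delay_s_s1) != self.n_depths_s1:
            raise ConfigurationError("S1 amplitude/delay length must match n_depths_s1")
        if min(min(self.amplitude_pct_m1), min(self.amplitude_pct_s1)) < 0:
            raise ConfigurationError("amplitudes must be >= 0")

    @staticmethod
    def _linear(lo: float, hi: float, n: int) -> tuple:
        return tuple(np.round(np.linspace(lo, hi, n), 6))

    def scale_at(self, freq_hz: float) -> float:
        return _freq_scale(dict(self.freq_scale), freq_hz)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: white Gaussian (optionally AR(1)) plus linear drift."""

    white_sd_pct: float = 0.15
    drift_pct_per_min: float = 0.1
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.white_sd_pct < 0:
            raise ConfigurationError("white_sd_pct must be >= 0")
        if not (0.0 <= self.ar1 < 1.0):
            raise ConfigurationError("ar1 must be in [0, 1)")


@dataclass
class SyntheticSession:
    """One simulated run: 4D volumes, label maps, glove trace and truth.

    ``volumes`` is (nx, ny, nz, n_volumes); ``roi_labels`` and
    ``depth_labels`` are (nx, ny, nz) with codes from :data:`ROI_CODES`
    (depth label −1 outside M1/S1).
    """

    volumes: np.ndarray
    affine: np.ndarray
    roi_labels: np.ndarray
    depth_labels: np.ndarray
    glove: GloveTrace
    paradigm: ParadigmSpec
    depth_spec: DepthSignalSpec
    noise_spec: NoiseSpec

    def roi_mask(self, roi: str) -> np.ndarray:
        return self.roi_labels == ROI_CODES[roi]

    def roi_series(self, roi: str) -> np.ndarray:
        """(n_voxels, n_volumes) raw series for one ROI."""
        return self.volumes[self.roi_mask(roi)]

    def roi_depths(self, roi: str) -> np.ndarray:
        """Per-voxel depth bin for the voxels returned by roi_series."""
        return self.depth_labels[self.roi_mask(roi)]


def _session_geometry(spec: DepthSignalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lay out ROI and depth label volumes on a small rectangular grid.

    Plane z indexes the compartment (M1, S1, control1, control2, CSF);
    x indexes depth within the cortical ROIs; y indexes voxels within a depth.
    Control ROIs are sized to match the M1 ROI, as in a matched-power design.
    """
    nx = max(spec.n_depths_m1, spec.n_depths_s1)
    ny = spec.voxels_per_depth
    roi = np.zeros((nx, ny, 5), dtype=np.int16)
    depth = np.full((nx, ny, 5), -1, dtype=np.int16)

    roi[: spec.n_depths_m1, :, 0] = ROI_CODES["M1"]
    depth[: spec.n_depths_m1, :, 0] = np.arange(spec.n_depths_m1)[:, None]
    roi[: spec.n_depths_s1, :, 1] = ROI_CODES["S1"]
    depth[: spec.n_depths_s1, :, 1] = np.arange(spec.n_depths_s1)[:, None]
    roi[: spec.n_depths_m1, :, 2] = ROI_CODES["control1"]
    roi[: spec.n_depths_m1, :, 3] = ROI_CODES["control2"]
    roi[0, :, 4] = ROI_CODES["CSF"]
    return roi, depth


def _steady_waveform(
    paradigm: ParadigmSpec, waveform: str, delays_s: np.ndarray
) -> np.ndarray:
    """Unit-fundamental-amplitude oscillation per delay, on the TR grid.

    Returns an array (n_delays, n_volumes).  For ``sinusoid`` the waveform is
    sin(2πf(t − lead_in − τ)); for ``hrf_boxcar`` the paradigm boxcar is
    convolved with the canonical HRF and rescaled so the fundamental
    amplitude of its steady-state portion is exactly 1 before per-depth
    scaling.
    """
    t = np.arange(paradigm.n_volumes) * paradigm.tr_s
    f = paradigm.stim_freq_hz
    delays = np.asarray(delays_s, dtype=float)

    if waveform == "sinusoid":
        return np.sin(
            2.0 * np.pi * f * (t[None, :] - paradigm.lead_in_off_s - delays[:, None])
        )

    # hrf_boxcar: convolve on a microtime grid, then shift and resample
    params = _hrf.HRFParams(dt_s=paradigm.tr_s / 16.0)
    kernel = _hrf.canonical_hrf(params)
    box = paradigm.boxcar(dt=params.dt_s)
    micro = np.convolve(box, kernel)[: len(box)]
    t_micro = np.arange(len(box)) * params.dt_s

    # calibrate on the undelayed steady-state portion (skip first 65 s)
    from .steady_state import discard_transient

    resp_tr = micro[:: int(round(paradigm.tr_s / params.dt_s))][: paradigm.n_volumes]
    ss, _, _ = discard_transient(resp_tr, paradigm.tr_s, paradigm.trial_onsets_s,
                                 paradigm.period_s)
    a0 = fundamental_amplitude(ss, paradigm.tr_s, f)
    if a0 <= 0:
        raise ConfigurationError("degenerate HRF-boxcar waveform")
    micro = (micro - micro.mean()) / a0
    out = np.empty((len(delays), paradigm.n_volumes))
    for i, tau in enumerate(delays):
        out[i] = np.interp(t - tau, t_micro, micro)
    return out


def simulate_session(
    paradigm: ParadigmSpec,
    depth_spec: DepthSignalSpec | None = None,
    noise_spec: NoiseSpec | None = None,
    glove_jitter_sd_s: float = 0.04,
) -> SyntheticSession:
    """Simulate one run: signal + drift + noise volumes, labels and glove.

    Per-voxel model: ``baseline × [1 + 0.01 · a_d · w(t − τ_d)] + drift +
    noise`` where w has unit fundamental amplitude.  Control-ROI voxels carry
    baseline, drift and noise only.  Deterministic given the specs' seed.
    """
    depth_spec = depth_spec or DepthSignalSpec()
    noise_spec = noise_spec or NoiseSpec()
    roi_labels, depth_labels = _session_geometry(depth_spec)
    nx, ny, nz = roi_labels.shape
    n_t = paradigm.n_volumes
    rng = np.random.default_rng(noise_spec.seed)

    scale = depth_spec.scale_at(paradigm.stim_freq_hz)
    vol = np.full((nx, ny, nz, n_t), BASELINE_SIGNAL, dtype=float)

    def add_signal(mask_plane: int, n_depths: int, amps, delays):
        w = _steady_waveform(paradigm, depth_spec.waveform, np.asarray(delays))
        for d in range(n_depths):
            m = depth_labels[:, :, mask_plane] == d
            vol[:, :, mask_plane, :][m] += (
                BASELINE_SIGNAL * 0.01 * float(amps[d]) * scale * w[d]
            )

    add_signal(0, depth_spec.n_depths_m1, depth_spec.amplitude_pct_m1,
               depth_spec.delay_s_m1)
    add_signal(1, depth_spec.n_depths_s1, depth_spec.amplitude_pct_s1,
               depth_spec.delay_s_s1)
    # CSF compartment
    w_csf = _steady_waveform(paradigm, depth_spec.waveform,
                             np.array([depth_spec.csf_delay_s]))[0]
    csf = roi_labels == ROI_CODES["CSF"]
    vol[csf] += BASELINE_SIGNAL * 0.01 * depth_spec.csf_amplitude_pct * scale * w_csf

    # drift + noise, on every voxel
    t = np.arange(n_t) * paradigm.tr_s
    drift = BASELINE_SIGNAL * 0.01 * noise_spec.drift_pct_per_min * (t / 60.0)
    vol += drift
    sd = BASELINE_SIGNAL * 0.01 * noise_spec.white_sd_pct
    if sd > 0:
        eps = rng.standard_normal((nx, ny, nz, n_t)) * sd
        if noise_spec.ar1 > 0:
            phi = noise_spec.ar1
            eps *= np.sqrt(1.0 - phi * phi)
            eps = _signal.lfilter([1.0], [1.0, -phi], eps, axis=-1)
        vol += eps

    glove = simulate_glove(paradigm, jitter_sd_s=glove_jitter_sd_s,
                           seed=noise_spec.seed + 1)
    affine = np.diag([1.1, 1.1, 1.1, 1.0])
    return SyntheticSession(
        volumes=vol, affine=affine, roi_labels=roi_labels,
        depth_labels=depth_labels, glove=glove, paradigm=paradigm,
        depth_spec=depth_spec, noise_spec=noise_spec,
    )


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def _spec_to_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    return json.loads(json.dumps(d, default=list))


def write_session(session: SyntheticSession, outdir: str | Path) -> dict[str, Path]:
    """Write a session as NIfTI volumes + label maps, glove TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": outdir / "bold.nii",
        "roi_labels": outdir / "roi_labels.nii",
        "depth_labels": outdir / "depth_labels.nii",
        "glove": outdir / "glove.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    nib.save(nib.Nifti1Image(session.volumes.astype(np.float32), session.affine),
             paths["bold"])
    aff3 = session.affine
    nib.save(nib.Nifti1Image(session.roi_labels.astype(np.int16), aff3),
             paths["roi_labels"])
    nib.save(nib.Nifti1Image(session.depth_labels.astype(np.int16), aff3),
             paths["depth_labels"])
    session.glove.to_tsv(paths["glove"])
    truth = {
        "paradigm": _spec_to_dict(session.paradigm),
        "depth_spec": _spec_to_dict(session.depth_spec),
        "noise_spec": _spec_to_dict(session.noise_spec),
        "roi_codes": ROI_CODES,
        "conventions": {
            "depth_index": "0 = white-matter interface, max = pial surface",
            "glove_amplitude_deg": "simulator convention (not measured)",
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["config"].write_text(yaml.safe_dump(truth, sort_keys=True))
    return paths


def read_session(indir: str | Path) -> SyntheticSession:
    """Reload a session written by :func:`write_session`."""
    indir = Path(indir)
    truth = json.loads((indir / "truth.json").read_text())
    par = ParadigmSpec(**truth["paradigm"])
    dspec = DepthSignalSpec(**{
        k: (tuple(map(tuple, v)) if k == "freq_scale" else
            tuple(v) if isinstance(v, list) else v)
        for k, v in truth["depth_spec"].items()
    })
    nspec = NoiseSpec(**truth["noise_spec"])
    bold = nib.load(indir / "bold.nii")
    return SyntheticSession(
        volumes=np.asarray(bold.dataobj, dtype=float),
        affine=bold.affine,
        roi_labels=np.asarray(nib.load(indir / "roi_labels.nii").dataobj).astype(np.int16),
        depth_labels=np.asarray(nib.load(indir / "depth_labels.nii").dataobj).astype(np.int16),
        glove=GloveTrace.from_tsv(indir / "glove.tsv"),
        paradigm=par, depth_spec=dspec, noise_spec=nspec,
    )
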
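"""End-to-end orchestration: simulate → detect → predict → analyze → depth.

One RunConfig drives the whole synthetic study: per-frequency sessions are
simulated with per-run seeds derived from a single global seed (a
counter-based spawn, so adding a run never perturbs earlier runs' data),
hand motion is detected from the glove traces, the ROI-level steady-state
analysis and the depth-resolved delay/cancellation analysis are run, and
everything is collected into one machine-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .depth import cancellation, delay_profile, depth_trial_set, fit_sine
from .hrf import predicted_frequency_response
from .kinematics import detect_motion
from .steady_state import (RoiTimeseries, amplitude_spectrum, discard_transient,
                           estimate_noise_floor, normalize_spectrum, peak_to_peak,
                           percent_signal_change, trial_average)
from .synth import (DepthSignalSpec, NoiseSpec, make_paradigm, simulate_session)

STUDY_FREQUENCIES = (0.05, 0.10, 0.20, 1.0 / 3.0, 0.50)
#: Runs per frequency: higher frequencies were repeated more to build SNR.
DEFAULT_N_RUNS = {0.05: 1, 0.10: 1, 0.20: 2, 1.0 / 3.0: 4, 0.50: 8}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one synthetic study end to end."""

    frequencies: tuple = STUDY_FREQUENCIES
    n_runs: tuple = tuple(sorted(DEFAULT_N_RUNS.items()))
    n_noise_runs: int = 2
    tr_s: float = 0.5
    n_volumes: int = 480
    lead_in_off_s: float = 0.0
    depth_spec: DepthSignalSpec = field(default_factory=DepthSignalSpec)
    white_sd_pct: float = 0.15
    drift_pct_per_min: float = 0.1
    ar1: float = 0.0
    glove_jitter_sd_s: float = 0.04
    seed: int = 0
    use_detected_onsets: bool = True
    noise_floor_run_counts: tuple = (1, 2, 10)
    ref_freq_hz: float = 0.05

    def __post_init__(self):
        for f in self.frequencies:
            if self.runs_for(f) < 1:
                raise ValueError(f"every frequency needs >= 1 run ({f} Hz)")

    def runs_for(self, freq_hz: float) -> int:
        for f, n in dict(self.n_runs).items():
            if np.isclose(f, freq_hz, rtol=0.02):
                return int(n)
        return 1

    def run_seed(self, stream: int, index: int) -> int:
        """Per-run seed from the global seed via a counter-based spawn."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream, index))
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_jsonable(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["frequencies"] = tuple(raw["frequencies"])
        raw["n_runs"] = tuple((float(f), int(n)) for f, n in raw["n_runs"])
        raw["noise_floor_run_counts"] = tuple(raw["noise_floor_run_counts"])
        ds = raw["depth_spec"]
        for k, v in ds.items():
            if isinstance(v, list):
                ds[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        raw["depth_spec"] = DepthSignalSpec(**ds)
        return cls(**raw)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    return obj


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _fkey(freq_hz: float) -> str:
    return f"{freq_hz:.6g}"


def _process_run(session, config: RunConfig):
    """Glove detection + per-ROI percent-signal-change with transient removal.

    Returns (roi_ts: {roi: RoiTimeseries on the truncated record},
    kinematics summary dict).  Trial onsets are the detected motion onsets
    when usable, else the nominal paradigm onsets, rebased to the truncated
    record.
    """
    paradigm = session.paradigm
    events = detect_motion(session.glove)
    nominal = paradigm.trial_onsets_s
    if (config.use_detected_onsets and events.n_blocks == len(nominal)
            and np.all(np.abs(events.block_onsets_s - nominal) < paradigm.on_s)):
        onsets = events.block_onsets_s
    else:
        onsets = nominal
    roi_ts = {}
    for roi in ("M1", "S1", "control1", "control2", "CSF"):
        pct = percent_signal_change(session.roi_series(roi))
        trunc, kept, start = discard_transient(pct, paradigm.tr_s, onsets,
                                               paradigm.period_s)
        roi_ts[roi] = RoiTimeseries(trunc, paradigm.tr_s,
                                    kept - start * paradigm.tr_s, roi_name=roi)
    kin = {
        "n_blocks": int(events.n_blocks),
        "grasp_freq_hz": float(events.grasp_freq_hz),
        "mean_flexions_per_block": float(np.mean(events.flexions_per_block))
        if events.n_blocks else 0.0,
    }
    return roi_ts, kin


def run_full_analysis(config: RunConfig | None = None) -> dict:
    """Execute every stage and return the report dictionary.

    Deterministic given the config (which includes the global seed); stage
    failures are re-raised as :class:`StageError` with the stage name.
    """
    config = config or RunConfig()
    report = {
        "provenance": {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "package_version": __version__,
            "config": _to_jsonable(config),
        },
        "schema_version": 1,
    }

    try:
        report["hrf_prediction"] = {
            _fkey(f): float(v)
            for f, v in predicted_frequency_response(
                config.frequencies, tr_s=config.tr_s, n_volumes=config.n_volumes,
                lead_in_off_s=config.lead_in_off_s,
                ref_freq_hz=config.ref_freq_hz,
            ).items()
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("hrf_prediction", str(e)) from e

    spectra = {}         # (roi, fkey) -> averaged AmplitudeSpectrum
    trial_avgs = {}      # (roi, fkey) -> TrialAverage
    depth_blocks = {}
    kin_summary = {}

    for fi, freq in enumerate(config.frequencies):
        fkey = _fkey(freq)
        try:
            paradigm = make_paradigm(freq, tr_s=config.tr_s,
                                     n_volumes=config.n_volumes,
                                     lead_in_off_s=config.lead_in_off_s)
            runs, kins = [], []
            for ri in range(config.runs_for(freq)):
                noise = NoiseSpec(white_sd_pct=config.white_sd_pct,
                                  drift_pct_per_min=config.drift_pct_per_min,
                                  ar1=config.ar1,
                                  seed=config.run_seed(fi, ri))
                session = simulate_session(paradigm, config.depth_spec, noise,
                                           glove_jitter_sd_s=config.glove_jitter_sd_s)
                roi_ts, kin = _process_run(session, config)
                runs.append((session, roi_ts))
                kins.append(kin)
            kin_summary[fkey] = {
                "n_blocks": int(np.sum([k["n_blocks"] for k in kins])),
                "grasp_freq_hz": float(np.mean([k["grasp_freq_hz"] for k in kins])),
                "mean_flexions_per_block": float(
                    np.mean([k["mean_flexions_per_block"] for k in kins])),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError(f"simulate@{fkey}Hz", str(e)) from e

        try:
            for roi in ("M1", "S1", "control1", "control2", "CSF"):
                per_run = [amplitude_spectrum(ts[roi]) for _, ts in runs]
                mean_amp = np.mean([s.amplitude for s in per_run], axis=0)
                spec = per_run[0]
                spec.amplitude = mean_amp
                spectra[(roi, fkey)] = spec
                trial_avgs[(roi, fkey)] = trial_average(
                    [ts[roi] for _, ts in runs], paradigm.period_s)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"steady_state@{fkey}Hz", str(e)) from e

        try:
            session0 = runs[0][0]
            csf_ta = trial_avgs[("CSF", fkey)]
            csf_fit = fit_sine(csf_ta.mean, csf_ta.time_s, paradigm.stim_freq_hz)
            depth_blocks[fkey] = {}
            for roi, n_bins in (("M1", config.depth_spec.n_depths_m1),
                                ("S1", config.depth_spec.n_depths_s1)):
                labels = session0.roi_depths(roi)
                dset = depth_trial_set(
                    [ts[roi].data for _, ts in runs], labels, n_bins,
                    config.tr_s, [ts[roi].trial_onsets_s for _, ts in runs],
                    paradigm.period_s, paradigm.stim_freq_hz, roi_name=roi)
                fits = [fit_sine(s, dset.time_s, paradigm.stim_freq_hz)
                        for s in dset.responses]
                prof = delay_profile(fits, csf_fit, paradigm.stim_freq_hz)
                canc = cancellation(dset)
                depth_blocks[fkey][roi] = {
                    "n_voxels": dset.n_voxels.tolist(),
                    "amplitude_pct": [f.amplitude for f in fits],
                    "phase_rad": prof.phase_rad.tolist(),
                    "delay_rel_csf_s": prof.delay_s.tolist(),
                    "cancellation": {
                        "depth_average_signal_change": canc.depth_average_signal_change,
                        "roi_average_signal_change": canc.roi_average_signal_change,
                        "cancellation": canc.cancellation,
                    },
                }
        except Exception as e:  # noqa: BLE001
            raise StageError(f"depth@{fkey}Hz", str(e)) from e

    # reference-normalized measured frequency response
    try:
        ref_key = _fkey(config.ref_freq_hz if any(
            np.isclose(config.ref_freq_hz, f, rtol=0.02) for f in config.frequencies
        ) else min(config.frequencies))
        freq_resp = {}
        for roi in ("M1", "S1", "control1", "control2"):
            ref_roi = "S1" if roi == "S1" else "M1"
            reference = spectra[(ref_roi, ref_key)]
            freq_resp[roi] = {}
            for freq in config.frequencies:
                fkey = _fkey(freq)
                norm = normalize_spectrum(spectra[(roi, fkey)], reference,
                                          ref_freq_hz=float(ref_key))
                freq_resp[roi][fkey] = {
                    "amplitude_pct": spectra[(roi, fkey)].value_at(freq),
                    "normalized": norm.value_at(freq),
                    "normalized_to": norm.normalized_to,
                }
        report["frequency_response"] = freq_resp
    except Exception as e:  # noqa: BLE001
        raise StageError("normalize", str(e)) from e

    # no-task noise floor (signal-free sessions, M1 ROI)
    try:
        quiet = replace(
            config.depth_spec,
            amplitude_pct_m1=tuple(0.0 for _ in range(config.depth_spec.n_depths_m1)),
            amplitude_pct_s1=tuple(0.0 for _ in range(config.depth_spec.n_depths_s1)),
            csf_amplitude_pct=0.0,
        )
        paradigm = make_paradigm(max(config.frequencies), tr_s=config.tr_s,
                                 n_volumes=config.n_volumes,
                                 lead_in_off_s=config.lead_in_off_s)
        no_task = []
        for ri in range(config.n_noise_runs):
            noise = NoiseSpec(white_sd_pct=config.white_sd_pct,
                              drift_pct_per_min=config.drift_pct_per_min,
                              ar1=config.ar1, seed=config.run_seed(1000, ri))
            session = simulate_session(paradigm, quiet, noise,
                                       glove_jitter_sd_s=0.0)
            pct = percent_signal_change(session.roi_series("M1"))
            trunc, kept, start = discard_transient(
                pct, config.tr_s, paradigm.trial_onsets_s, paradigm.period_s)
            no_task.append(RoiTimeseries(trunc, config.tr_s,
                                         kept - start * config.tr_s, "M1"))
        floor = estimate_noise_floor(no_task, config.noise_floor_run_counts)
        nz = floor.freq_hz > 0
        report["noise_floor"] = {
            "mean_level_pct": float(floor.single_run[nz].mean()),
            "at_stimulus_freqs": {
                _fkey(f): float(
                    floor.single_run[np.argmin(np.abs(floor.freq_hz - f))])
                for f in config.frequencies
            },
            "scaled_mean_level_pct": {
                str(n): float(v[nz].mean()) for n, v in floor.scaled.items()
            },
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("noise_floor", str(e)) from e

    report["kinematics"] = kin_summary
    report["trial_averages"] = {
        roi: {
            fkey: {
                "time_s": ta.time_s.tolist(),
                "mean_pct": ta.mean.tolist(),
                "ci95_pct": ta.ci95.tolist(),
                "peak_to_peak_pct": peak_to_peak(ta),
                "n_voxels": ta.n_voxels,
                "n_runs": ta.n_runs,
            }
            for (r, fkey), ta in trial_avgs.items() if r == roi
        }
        for roi in ("M1", "S1", "control1", "control2", "CSF")
    }
    report["depth"] = depth_blocks
    return report


REQUIRED_BLOCKS = ("provenance", "hrf_prediction", "frequency_response",
                   "noise_floor", "trial_averages", "depth", "kinematics")


def validate_report(report: dict) -> None:
    """Schema check: every required block present, cancellation included."""
    for key in REQUIRED_BLOCKS:
        if key not in report:
            raise ValueError(f"report missing block {key!r}")
    for fkey, rois in report["depth"].items():
        for roi, blk in rois.items():
            if "cancellation" not in blk:
                raise ValueError(f"depth block {roi}@{fkey} missing cancellation")


def write_report(report: dict, outdir: str | Path) -> dict[str, Path]:
    """Write the report JSON plus flat TSV tables."""
    validate_report(report)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"report": outdir / "report.json"}
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True))

    rows = []
    for roi, freqs in report["frequency_response"].items():
        for fkey, vals in freqs.items():
            rows.append({"roi": roi, "freq_hz": float(fkey),
                         "hrf_predicted": report["hrf_prediction"].get(fkey),
                         **{k: v for k, v in vals.items()}})
    paths["frequency_response"] = outdir / "frequency_response.tsv"
    pd.DataFrame(rows).sort_values(["roi", "freq_hz"]).to_csv(
        paths["frequency_response"], sep="\t", index=False)

    rows = []
    for fkey, rois in report["depth"].items():
        for roi, blk in rois.items():
            for d in range(len(blk["n_voxels"])):
                rows.append({
                    "roi": roi, "freq_hz": float(fkey), "depth_bin": d,
                    "n_voxels": blk["n_voxels"][d],
                    "amplitude_pct": blk["amplitude_pct"][d],
                    "phase_rad": blk["phase_rad"][d],
                    "delay_rel_csf_s": blk["delay_rel_csf_s"][d],
                })
    paths["depth_profiles"] = outdir / "depth_profiles.tsv"
    pd.DataFrame(rows).to_csv(paths["depth_profiles"], sep="\t", index=False)

    rows = []
    for fkey, rois in report["depth"].items():
        for roi, blk in rois.items():
            rows.append({"roi": roi, "freq_hz": float(fkey),
                         **blk["cancellation"]})
    paths["cancellation"] = outdir / "cancellation.tsv"
    pd.DataFrame(rows).sort_values(["roi", "freq_hz"]).to_csv(
        paths["cancellation"], sep="\t", index=False)
    return paths


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
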
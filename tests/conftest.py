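import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from boldwave import synth  # noqa: E402
from boldwave.steady_state import (RoiTimeseries, discard_transient,  # noqa: E402
                                   percent_signal_change)


@pytest.fixture(scope="session")
def paradigms():
    """One ParadigmSpec per study frequency (default run geometry)."""
    return {f: synth.make_paradigm(f) for f in (0.05, 0.10, 0.20, 1 / 3, 0.50)}


@pytest.fixture(scope="session")
def noiseless_session():
    """Sinusoid-waveform session with zero noise and drift (0.2 Hz)."""
    par = synth.make_paradigm(0.2)
    dspec = synth.DepthSignalSpec(voxels_per_depth=2)
    nspec = synth.NoiseSpec(white_sd_pct=0.0, drift_pct_per_min=0.0, seed=0)
    return synth.simulate_session(par, dspec, nspec, glove_jitter_sd_s=0.0)


def roi_steady_pct(session, roi):
    """Percent-signal-change ROI record after transient removal (helper)."""
    par = session.paradigm
    pct = percent_signal_change(session.roi_series(roi))
    trunc, kept, start = discard_transient(pct, par.tr_s, par.trial_onsets_s,
                                           par.period_s)
    return RoiTimeseries(trunc, par.tr_s, kept - start * par.tr_s, roi_name=roi)
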
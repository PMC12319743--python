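#!/usr/bin/env python
"""Full synthetic study: simulate -> detect -> analyze -> depth -> report.

Runs the default configuration (five stimulus frequencies, 1/1/2/4/8 runs,
7 S1 + 15 M1 depth bins, white noise + drift, jittered glove traces) and
writes the machine-readable report plus flat tables under results/.

Findings on the default synthetic truth: the measured normalized frequency
response sits far above the canonical-HRF prediction at high frequency
(~50x at 0.5 Hz); control ROIs stay at the noise floor; depth-resolved
phase cancellation grows monotonically with stimulus frequency and is
stronger in M1 (15 bins, delays spanning 0.5 s) than in S1.
"""

from pathlib import Path

import pandas as pd

from boldwave.pipeline import RunConfig, run_full_analysis, write_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    config = RunConfig(seed=1)
    report = run_full_analysis(config)
    paths = write_report(report, OUT)

    fr = pd.read_csv(paths["frequency_response"], sep="\t")
    print("Normalized frequency response (measured vs canonical prediction):")
    print(fr[fr.roi.isin(["M1", "S1"])][
        ["roi", "freq_hz", "normalized", "hrf_predicted"]].to_string(index=False))

    canc = pd.read_csv(paths["cancellation"], sep="\t")
    print("\nPhase cancellation vs stimulus frequency:")
    print(canc.to_string(index=False))

    nf = report["noise_floor"]
    print(f"\nSingle-run noise floor (mean over bins): "
          f"{nf['mean_level_pct']:.4f}% ; scaled: {nf['scaled_mean_level_pct']}")
    print(f"\nReport written to {paths['report']}")


if __name__ == "__main__":
    main()
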
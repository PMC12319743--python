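#!/usr/bin/env python
"""Diagnostic figures from the synthetic-study report.

Reads results/report.json (run analysis/03 first) and plots the normalized
frequency response with the canonical prediction and noise floors, the
depth amplitude and delay profiles, and cancellation vs frequency.
Figures are written to scratch/figures/ (they are diagnostics, not
deliverable tables).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from boldwave.pipeline import read_report

ROOT = Path(__file__).resolve().parents[1]
FIGDIR = ROOT / "scratch" / "figures"


def main():
    report = read_report(ROOT / "results" / "report.json")
    FIGDIR.mkdir(parents=True, exist_ok=True)
    fkeys = sorted(report["hrf_prediction"], key=float)
    freqs = [float(k) for k in fkeys]

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogy(freqs, [report["hrf_prediction"][k] for k in fkeys],
                "k--", label="canonical HRF")
    for roi, color in (("M1", "tab:blue"), ("S1", "tab:red"),
                       ("control1", "tab:gray")):
        ax.semilogy(freqs,
                    [report["frequency_response"][roi][k]["normalized"]
                     for k in fkeys], "o-", color=color, label=roi)
    floor = report["noise_floor"]["at_stimulus_freqs"]
    m1_ref = report["frequency_response"]["M1"][fkeys[0]]["amplitude_pct"]
    ax.semilogy(freqs, [floor[k] / m1_ref for k in fkeys], color="tab:green",
                alpha=0.6, label="noise floor (1 run)")
    ax.set_xlabel("stimulus frequency (Hz)")
    ax.set_ylabel("amplitude / 0.05-Hz reference")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(FIGDIR / "frequency_response.png", dpi=120)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    for k in fkeys:
        m1 = report["depth"][k]["M1"]
        x = np.arange(len(m1["amplitude_pct"]))
        axes[0].plot(x, m1["amplitude_pct"], "o-", label=f"{k} Hz")
        axes[1].plot(x, m1["delay_rel_csf_s"], "o-")
    axes[0].set(xlabel="M1 depth bin (WM->pial)", ylabel="amplitude (%)")
    axes[0].set_yscale("log")
    axes[0].legend(fontsize=7)
    axes[1].set(xlabel="M1 depth bin (WM->pial)", ylabel="delay rel. CSF (s)")
    for roi, color in (("M1", "tab:blue"), ("S1", "tab:red")):
        axes[2].plot(freqs,
                     [report["depth"][k][roi]["cancellation"]["cancellation"]
                      for k in fkeys], "o-", color=color, label=roi)
    axes[2].set(xlabel="stimulus frequency (Hz)", ylabel="cancellation")
    axes[2].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(FIGDIR / "depth_profiles.png", dpi=120)
    print(f"Figures written to {FIGDIR}")


if __name__ == "__main__":
    main()
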
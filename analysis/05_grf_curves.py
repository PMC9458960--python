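#!/usr/bin/env python
"""Ground reaction forces: overground versus a weak-belt treadmill.

Extracts cycle-normalized right-foot GRF curves from an overground trial
and a 300 N / 10 Hz treadmill trial at 1.05 m/s.  The horizontal
(braking/propulsive) component carries the belt's speed fluctuations
back into the gait, which is the causal path behind every kinematic
difference in this pipeline.  Writes results/grf_curves.csv and, if
matplotlib is available, a figure under scratch/figures/.
"""

import os

import numpy as np
import pandas as pd

from treadgait import TreadmillSpec, TrialConfig, extract_grf, run_trial

ROOT = os.path.join(os.path.dirname(__file__), "..")
OUT = os.path.join(ROOT, "results")


def main():
    os.makedirs(OUT, exist_ok=True)
    og = run_trial(TrialConfig(speed=1.05, duration=12.0))
    tm = run_trial(TrialConfig(speed=1.05, duration=12.0,
                               treadmill=TreadmillSpec(1.05, fmax=300.0,
                                                       fctrl=10.0)))
    curves = {"overground": extract_grf(og, "R"), "treadmill": extract_grf(tm, "R")}
    pct = np.linspace(0.0, 100.0, len(curves["overground"]["vertical"]))
    df = pd.DataFrame({
        "pct_cycle": pct,
        "og_horizontal_N": curves["overground"]["horizontal"],
        "og_vertical_N": curves["overground"]["vertical"],
        "tm_horizontal_N": curves["treadmill"]["horizontal"],
        "tm_vertical_N": curves["treadmill"]["vertical"],
    })
    df.to_csv(os.path.join(OUT, "grf_curves.csv"), index=False)
    print(f"peak braking force: overground "
          f"{curves['overground']['horizontal'].min():.0f} N, treadmill "
          f"{curves['treadmill']['horizontal'].min():.0f} N")
    print(f"cycle-mean vertical GRF (both trials should be near body "
          f"weight 618 N): og {curves['overground']['vertical'].mean() * 2:.0f}, "
          f"tm {curves['treadmill']['vertical'].mean() * 2:.0f}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    figdir = os.path.join(ROOT, "scratch", "figures")
    os.makedirs(figdir, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, comp in zip(axes, ("horizontal", "vertical")):
        ax.plot(pct, curves["overground"][comp], label="overground")
        ax.plot(pct, curves["treadmill"][comp], "--", label="treadmill 300 N/10 Hz")
        ax.set_xlabel("% gait cycle")
        ax.set_ylabel(f"{comp} GRF (N)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(os.path.join(figdir, "grf_curves.png"), dpi=150)
    print(f"figure written to {figdir}/grf_curves.png")


if __name__ == "__main__":
    main()
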
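#!/usr/bin/env python
"""Render the mechanism prediction panels (choice probability and mean
decision time versus background count) for the illustration baseline.

    python scripts/plot_predictions.py --out scratch/predictions.png
"""

from __future__ import annotations

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from odorddm.interference import HypothesisSpec, prediction_table
from odorddm.params import DDMParameters

BASE_ON = DDMParameters(1.0, 0.0, 2.0, 3.0)
BASE_OFF = DDMParameters(1.0, 0.0, -2.5, 3.0)
COLORS = {"target_on": "tab:blue", "target_off": "tab:red"}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("scratch/predictions.png"))
    args = ap.parse_args()

    mechanisms = ["false_signal", "signal_reduction", "noise_boost"]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
    for ax, mech in zip(axes[:3], mechanisms):
        table = prediction_table(HypothesisSpec(mech, BASE_ON, BASE_OFF), range(7))
        for tt, sub in table.groupby("trial_type"):
            sub = sub.sort_values("n_background")
            ax.plot(sub["n_background"], sub["p"], "o-", color=COLORS[tt], label=tt)
        ax.set_title(mech.replace("_", " "))
        ax.set_xlabel("# background odorants")
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("p(report present)")
    axes[0].legend(frameon=False, fontsize=8)

    table = prediction_table(
        HypothesisSpec("noise_boost", BASE_ON, BASE_OFF), range(7)
    )
    for tt, sub in table.groupby("trial_type"):
        sub = sub.sort_values("n_background")
        axes[3].plot(
            sub["n_background"], sub["mean_dt"], "o-", color=COLORS[tt], label=tt
        )
    axes[3].set_title("noise boost: mean decision time")
    axes[3].set_xlabel("# background odorants")
    axes[3].set_ylabel("E[DT] (s)")

    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
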
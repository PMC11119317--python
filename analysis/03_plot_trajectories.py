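#!/usr/bin/env python
"""Plot genetic-progress trajectories per method, one line per switch stage.

Reads results/trajectories.csv and writes results/figures/<method>.png with
one panel per (h2, R) cell present in the data: replicate-averaged mean IC
GV of the 36 elite-trial combinations against breeding cycle.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = pd.read_csv(ROOT / "trajectories.csv")
    figdir = ROOT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    for method, dm in data.groupby("method"):
        cells = sorted(dm.groupby(["h2", "R"]).groups)
        fig, axes = plt.subplots(
            1, len(cells), figsize=(4 * len(cells), 3.2), squeeze=False, sharey=True
        )
        for ax, (h2, r) in zip(axes[0], cells):
            cell = dm[(dm["h2"] == h2) & (dm["R"] == r)]
            for switch, ds in cell.groupby("switch_stage"):
                m = ds.groupby("cycle")["mean_ic_gv"].mean().sort_index()
                ax.plot(m.index, m.values, marker="o", ms=3, label=f"switch at {switch}")
            ax.set_title(f"{method}: h²={h2:g}, R={r:g}")
            ax.set_xlabel("breeding cycle")
        axes[0][0].set_ylabel("mean IC GV of 36 EYT combinations")
        axes[0][-1].legend(frameon=False, fontsize=8)
        fig.tight_layout()
        out = figdir / f"{method.lower()}_trajectories.png"
        fig.savefig(out, dpi=150)
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
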
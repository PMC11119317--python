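#!/usr/bin/env python
"""Summarize the scenario trajectories and report the scheme orderings.

Reads results/trajectories.csv (written by 01_run_scenarios.py), writes
results/summary.csv (asymptotic mean IC GV, convergence cycle, early gain
rate per scenario) and prints which switch stage wins per method and
correlation level.
"""

from pathlib import Path

import pandas as pd

from icbreedsim.experiment import detect_convergence

ROOT = Path(__file__).resolve().parents[1] / "results"
KEYS = ["method", "h2", "R", "switch_stage"]


def main() -> None:
    data = pd.read_csv(ROOT / "trajectories.csv")
    rows = []
    for key, df in data.groupby(KEYS):
        m = df.groupby("cycle")["mean_ic_gv"].mean().sort_index().to_numpy()
        v = df.groupby("cycle")["var_ic_gv"].mean().sort_index().to_numpy()
        conv = detect_convergence(m)
        rows.append(
            dict(
                zip(KEYS, key),
                asymptotic_mean_ic_gv=m[-1],
                convergence_cycle=conv.cycle,
                early_gain_rate=(m[min(5, m.size) - 1] - m[0]) / (min(5, m.size) - 1),
                variance_depletion=v[-1] / v[0],
            )
        )
    summary = pd.DataFrame(rows).sort_values(KEYS)
    summary.to_csv(ROOT / "summary.csv", index=False)
    print(summary.to_string(index=False))

    print("\nBest switch stage per (method, R), by asymptotic mean IC GV:")
    for (method, r), df in summary.groupby(["method", "R"]):
        best = df.loc[df["asymptotic_mean_ic_gv"].idxmax()]
        print(f"  {method:3s} R={r:g}: {best['switch_stage']} "
              f"(asymptote {best['asymptotic_mean_ic_gv']:.3f})")


if __name__ == "__main__":
    main()
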
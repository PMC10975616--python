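#!/usr/bin/env python
"""Per-run kinematic measurements for the simulated experiment.

Reads the recordings written by 01_simulate.py, runs the full measurement
chain (crossing point, speeds, braking category, rotation events, stance
feet) and writes the per-run results table.
"""

from pathlib import Path

import pandas as pd

from bottleneck_gait.pipeline import analyze_run
from bottleneck_gait.trajectory_model import read_run_recording, write_results

ROOT = Path(__file__).resolve().parents[1]
REC_DIR = ROOT / "scratch" / "recordings"
RESULTS = ROOT / "results"


def main() -> None:
    files = sorted(REC_DIR.glob("*.csv"))
    if not files:
        raise SystemExit("no recordings found — run analysis/01_simulate.py first")
    rows = []
    for f in files:
        res = analyze_run(read_run_recording(f))
        rows.append(res.to_row())
    runs = pd.DataFrame(rows)
    write_results(runs, RESULTS / "run_results.csv")
    n_onset = runs["onset_d"].notna().sum()
    print(f"analyzed {len(runs)} runs; rotation onset detected in {n_onset} "
          f"({n_onset / len(runs):.0%})")
    print("median vmax by motivation:")
    print(runs.groupby("motivation")["vmax"].median().round(3).to_string())
    print(f"results: {RESULTS / 'run_results.csv'}")


if __name__ == "__main__":
    main()
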
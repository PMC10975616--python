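#!/usr/bin/env python
"""Cross-run statistics for the simulated experiment.

Reads the recordings again to build speed/rotation profiles alongside the
per-run table, then fits the crossing-offset law, the exponential
amplitude-vs-R law with its critical ratio R_crit, the braking histogram and
the significance-masked correlation matrices.
"""

from pathlib import Path

import pandas as pd

from bottleneck_gait.pipeline import analyze_experiment
from bottleneck_gait.trajectory_model import read_run_recording, write_results

ROOT = Path(__file__).resolve().parents[1]
REC_DIR = ROOT / "scratch" / "recordings"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    files = sorted(REC_DIR.glob("*.csv"))
    if not files:
        raise SystemExit("no recordings found — run analysis/01_simulate.py first")
    tables = analyze_experiment(read_run_recording(f) for f in files)
    TABLES.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame) and len(table):
            write_results(table, TABLES / f"{name}.csv")
        elif isinstance(table, dict):
            for split, mat in table.items():
                if isinstance(mat, pd.DataFrame):
                    safe = split.replace("<=", "_le_").replace(">", "_gt_")
                    mat.to_csv(TABLES / f"{name}_{safe}.csv")

    laws = tables["crossing_laws"]
    if len(laws):
        print("crossing-offset law (side-folded offset vs width):")
        for _, row in laws.iterrows():
            print(f"  {row['motivation']:>8}: slope {row['slope']:+.3f} m/m, "
                  f"intercept {row['intercept']:+.3f} m "
                  f"-> {row['shift_per_10cm_cm']:.2f} cm per 10 cm of width")
    fits = tables["rotation_fits"]
    if len(fits):
        print("critical ratio R_crit by angle and motivation:")
        piv = fits.pivot_table(index="angle_deg", columns="motivation",
                               values="rcrit")
        print(piv.round(2).to_string())
    print(f"tables: {TABLES}")


if __name__ == "__main__":
    main()
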
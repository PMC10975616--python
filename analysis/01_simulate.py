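#!/usr/bin/env python
"""Generate the synthetic bottleneck experiment.

Full factorial over 7 approach angles x 6 bottleneck widths x 2 motivation
conditions (one bottleneck length; the study pooled lengths), one run per
participant and cell.  Recordings go to scratch/recordings (large,
regenerable); the ground-truth table goes to results/.
"""

from pathlib import Path

from bottleneck_gait.synthetic import (SyntheticConfig, generate_experiment,
                                       ground_truth_table)
from bottleneck_gait.trajectory_model import write_results, write_run_recording

ROOT = Path(__file__).resolve().parents[1]
REC_DIR = ROOT / "scratch" / "recordings"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = SyntheticConfig(seed=20240601, lengths=(1.0,), n_participants=13,
                          n_per_cell=2)
    REC_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    gts = []
    for rec, gt in generate_experiment(cfg):
        write_run_recording(rec, REC_DIR / f"{rec.meta.run_id}.csv")
        gts.append(gt)
    table = ground_truth_table(gts)
    write_results(table, RESULTS / "ground_truth.csv")
    print(f"simulated {len(gts)} runs "
          f"({table['decel_category'].value_counts().to_dict()})")
    print(f"recordings: {REC_DIR}")
    print(f"ground truth: {RESULTS / 'ground_truth.csv'}")


if __name__ == "__main__":
    main()
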
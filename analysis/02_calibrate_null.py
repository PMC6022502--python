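#!/usr/bin/env python
"""Calibrate scan significance thresholds on neutral coalescent replicates.

Simulates sweep-free cohorts under the default dog/wolf demographic model,
scans each replicate exactly as the real cohort is scanned, pools the window
values, and writes the 99th-percentile F_ST and XP-CLR thresholds and the
0.1th-percentile H_P thresholds to results/calibration.json. Also reports
held-out false-positive rates so the calibration can be sanity-checked.
"""

import argparse
import json
from pathlib import Path

import domestiscan.workflows as wf


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--reps", type=int, default=25)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    print(f"simulating {args.reps} neutral replicates "
          f"({sum(wf.calibration_chroms().values())/1e6:.0f} Mb each)")
    calib = wf.run_calibration(seed=args.seed, reps=args.reps)
    rates = wf.heldout_flag_rates(seed=args.seed + 1, calib=calib, reps=3)

    out = {
        "fst_q99": calib.fst_q99,
        "xpclr_q99": calib.xpclr_q99,
        "hp_q01_fstwin": calib.hp_q01_fstwin,
        "hp_q01_xpwin": calib.hp_q01_xpwin,
        "n_replicates": calib.n_replicates,
        "pooled_window_counts": calib.pooled_counts,
        "heldout_flag_rates": rates,
        "seed": args.seed,
    }
    args.results.mkdir(parents=True, exist_ok=True)
    with open(args.results / "calibration.json", "w") as fh:
        json.dump(out, fh, indent=2)

    print(f"thresholds: F_ST(q99)={calib.fst_q99:.4f}  "
          f"XP-CLR(q99)={calib.xpclr_q99:.2f}  "
          f"H_P(q0.1, 25kb)={calib.hp_q01_xpwin:.4f}  "
          f"H_P(q0.1, 200kb)={calib.hp_q01_fstwin:.4f}")
    for stat, r in rates.items():
        print(f"held-out {stat}: {r['flagged']}/{r['n']} windows flagged")


if __name__ == "__main__":
    main()
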
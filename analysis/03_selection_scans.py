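#!/usr/bin/env python
"""Run the F_ST and XP-CLR candidate cascades on the benchmark cohort.

Regenerates the cohort of 01_simulate_cohort.py (same seed), applies the
calibrated thresholds from results/calibration.json plus the pooled
heterozygosity and ancient-dog ΔHp filters, merges passing windows into
candidate regions, and scores them against the planted-sweep truth.
"""

import argparse
import json
from pathlib import Path

import domestiscan as ds
import domestiscan.workflows as wf


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    with open(args.results / "calibration.json") as fh:
        c = json.load(fh)
    calib = wf.CalibrationBundle(
        fst_q99=c["fst_q99"], xpclr_q99=c["xpclr_q99"],
        hp_q01_fstwin=c["hp_q01_fstwin"], hp_q01_xpwin=c["hp_q01_xpwin"],
        n_replicates=c["n_replicates"],
    )

    chroms = wf.sweep_chroms()
    sweeps = wf.default_sweeps()
    cohort = ds.generate_cohort(wf.study_model(), chroms, sweeps=sweeps,
                                n_dogs=wf.N_DOGS, n_wolves=wf.N_WOLVES,
                                seed=args.seed, n_ancient=wf.N_ANCIENT)
    anc = ds.generate_ancient_samples(cohort, wf.N_ANCIENT, seed=args.seed + 1)

    summary = {}
    for which in ("fst", "xpclr"):
        regions = wf.scan_cascade(cohort, calib, anc, which=which)
        bed = args.results / f"{which}_candidates.bed"
        regions[["chrom", "start", "end", "peak", "n_windows"]].to_csv(
            bed, sep="\t", header=False, index=False
        )
        hits = sum(
            ((regions["chrom"] == s.chrom) & (regions["start"] < s.end)
             & (regions["end"] > s.start)).any()
            for s in sweeps
        )
        false = sum(
            not any(s.chrom == r.chrom and s.start < r.end and s.end > r.start
                    for s in sweeps)
            for r in regions.itertuples(index=False)
        )
        summary[which] = {
            "candidate_regions": int(len(regions)),
            "sweeps_recovered": int(hits),
            "false_regions": int(false),
        }
        print(f"{which}: {len(regions)} candidate regions; "
              f"{hits}/{len(sweeps)} sweeps recovered, {false} unexplained")

    with open(args.results / "scan_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
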
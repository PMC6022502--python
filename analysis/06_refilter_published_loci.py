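#!/usr/bin/env python
"""Re-evaluate externally published candidate loci under this cohort's
filter cascade.

Emulates the reassessment of previously published candidate domestication
regions: a BED of "legacy" loci (here: the planted sweeps, standing in for
loci that do replicate, plus random neutral intervals, standing in for loci
that do not) is intersected with the cohort's F_ST scan windows, and each
locus keeps or loses its candidate status under the maximum-F_ST / H_P /
ΔHp thresholds.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import domestiscan as ds
import domestiscan.workflows as wf
from domestiscan.fst_scan import fst_sites, windowed_fst
from domestiscan.genome_windows import make_windows
from domestiscan.heterozygosity import window_hp
from domestiscan.legacy_loci import refilter_loci


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    with open(args.results / "calibration.json") as fh:
        c = json.load(fh)

    chroms = wf.sweep_chroms()
    sweeps = wf.default_sweeps()
    cohort = ds.generate_cohort(wf.study_model(), chroms, sweeps=sweeps,
                                n_dogs=wf.N_DOGS, n_wolves=wf.N_WOLVES,
                                seed=args.seed, n_ancient=wf.N_ANCIENT)
    anc = ds.generate_ancient_samples(cohort, wf.N_ANCIENT, seed=args.seed + 1)
    af, ancf = wf.prepare_frequencies(cohort.variants, cohort.panel, anc)

    windows = make_windows(chroms, wf.FST_WIN, wf.FST_STEP)
    fw = windowed_fst(fst_sites(af), windows, min_snps=wf.FST_MIN_SNPS)
    hp = window_hp(af, fw[["chrom", "start", "end"]], ancient_gt=ancf)
    fw = fw.assign(hp=hp["hp"].to_numpy(), delta_hp=hp["delta_hp"].to_numpy())
    dhp_thr = min(
        float(np.nanpercentile(fw["delta_hp"], wf.DHP_PERCENTILE)), wf.DHP_CAP
    )

    rng = np.random.default_rng(args.seed + 7)
    replicating = [
        {"source": "replicates", "chrom": s.chrom, "start": s.start, "end": s.end}
        for s in sweeps[:5]
    ]
    random_loci = [
        {
            "source": "background",
            "chrom": f"chr{rng.integers(1, 6)}",
            "start": (start := int(rng.integers(0, 9_500_000))),
            "end": start + 400_000,
        }
        for _ in range(10)
    ]
    loci = pd.DataFrame(replicating + random_loci)

    report = refilter_loci(loci, fw, fst_threshold=c["fst_q99"],
                           hp_threshold=c["hp_q01_fstwin"], dhp_threshold=dhp_thr)
    report.to_csv(args.results / "legacy_refilter.tsv", sep="\t", index=False)
    by_source = report.groupby("source")["passes"].agg(["sum", "count"])
    print(by_source)
    print("loci overlapping true sweeps should pass; random background "
          "loci should fail the cascade")


if __name__ == "__main__":
    main()
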
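#!/usr/bin/env python
"""Simulate the benchmark cohort: 43 village dogs, 10 wolves, 2 ancient dogs
on a 50-Mb genome (5 x 10-Mb chromosomes) with ten planted 400-kb
fixed-haplotype sweeps, per-sample 3-kb read-depth tracks carrying one
dog-specific duplication, and a toy gene/GO annotation.

Large raw outputs (VCF, depth tracks) go to scratch/cohort/; a small summary
lands in results/.
"""

import argparse
import json
from pathlib import Path

import domestiscan as ds
import domestiscan.workflows as wf
from domestiscan.synthetic_data import CnvSpec, generate_toy_annotation


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    chroms = wf.sweep_chroms()
    sweeps = wf.default_sweeps()
    print(f"simulating {sum(chroms.values())/1e6:.0f} Mb cohort "
          f"({wf.N_DOGS} dogs, {wf.N_WOLVES} wolves) with {len(sweeps)} sweeps")
    cohort = ds.generate_cohort(wf.study_model(), chroms, sweeps=sweeps,
                                n_dogs=wf.N_DOGS, n_wolves=wf.N_WOLVES,
                                seed=args.seed, n_ancient=wf.N_ANCIENT)
    anc = ds.generate_ancient_samples(cohort, wf.N_ANCIENT, seed=args.seed + 1)
    cohort.write(args.scratch, ancient_gt=anc)

    cnv = CnvSpec("chr1", 4_000_000, 4_009_000, {"dog": {4: 1.0}, "wolf": {2: 1.0}})
    tracks = ds.generate_depth_profiles(cohort.panel, chroms, [cnv],
                                        seed=args.seed + 2, noise_sd=0.05)
    tracks.write(args.scratch / "depth")

    genes, annot, onto = generate_toy_annotation(chroms, n_genes=400,
                                                 ontology_depth=3, n_terms=40,
                                                 seed=args.seed + 3)
    genes.to_csv(args.scratch / "genes.bed", sep="\t", header=False, index=False)
    annot.to_csv(args.scratch / "annotations.tsv", sep="\t", index=False)
    onto.to_csv(args.scratch / "ontology.tsv", sep="\t", index=False)

    args.results.mkdir(parents=True, exist_ok=True)
    summary = {
        "seed": args.seed,
        "genome_mb": sum(chroms.values()) / 1e6,
        "n_sites": int(cohort.variants.n_sites),
        "n_sweeps": len(sweeps),
        "n_genes": int(len(genes)),
        "n_terms": int(onto["child"].nunique()) + 1 if len(onto) else 1,
        "depth_windows": int(len(tracks.windows)),
    }
    with open(args.results / "cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"cohort: {summary['n_sites']} SNPs; wrote raw data to {args.scratch}, "
          f"summary to {args.results / 'cohort_summary.json'}")


if __name__ == "__main__":
    main()
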
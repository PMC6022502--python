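"""Neutral-simulation calibration of scan significance thresholds.

Instead of arbitrary Z cutoffs, scan thresholds are calibrated on neutral
coalescent replicates of the cohort's demographic history: each replicate is
scanned with exactly the parameters used on the real data, the window values
are pooled over replicates, and the threshold is the requested percentile of
the pooled distribution (99th for F_ST and XP-CLR, 0.1th for H_P). Simulated
SNP sets pass the same minor-allele-count filter as the real data and can be
randomly thinned to the real per-chromosome SNP counts so that window SNP
densities match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .demography import DemographicModel
from .genome_windows import percentile_threshold
from .synthetic_data import generate_cohort
from .variant_io import SamplePanel, VariantTable, maf_filter

__all__ = ["CalibrationResult", "simulate_neutral", "match_real_snps", "calibrate_threshold"]


@dataclass
class CalibrationResult:
    """A calibrated percentile threshold and its provenance."""

    statistic: str
    q: float
    threshold: float
    n_replicates: int
    per_replicate_counts: list[int] = field(default_factory=list)
    pooled_values: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def simulate_neutral(
    model: DemographicModel,
    chrom_lengths: dict[str, int],
    reps: int = 75,
    seeds: Sequence[int] | None = None,
    n_dogs: int = 43,
    n_wolves: int = 10,
    seed: int | None = None,
) -> list[tuple[VariantTable, SamplePanel]]:
    """Neutral genotype replicates under the demographic model.

    ``seeds`` must be distinct (one per replicate); alternatively pass a
    single ``seed`` from which replicate seeds are derived. Each replicate
    holds ``n_dogs + n_wolves`` diploids and no sweeps.
    """
    model.validate()
    if seeds is None:
        if seed is None:
            raise ValueError("provide either seeds or a master seed")
        rng = np.random.default_rng(seed)
        seeds = [int(s) for s in rng.integers(1, 2**31 - 1, size=reps)]
    seeds = list(seeds)
    if len(seeds) != reps:
        raise ValueError(f"need {reps} seeds, got {len(seeds)}")
    if len(set(seeds)) != len(seeds):
        raise ValueError("replicate seeds must be distinct")
    out = []
    for s in seeds:
        cohort = generate_cohort(
            model, chrom_lengths, sweeps=(), n_dogs=n_dogs, n_wolves=n_wolves,
            seed=s, n_ancient=2,
        )
        out.append((cohort, cohort.panel))
    return out


def match_real_snps(
    sim: VariantTable,
    panel: SamplePanel,
    real_counts: dict[str, int],
    min_minor_count: int = 3,
    seed: int = 0,
) -> VariantTable:
    """Apply the cohort MAF rule, then thin to the real per-chromosome counts.

    Thinning is uniform without replacement (seeded), preserving position
    order, so the simulated allele-frequency spectrum shape is retained.
    """
    filtered = maf_filter(sim, panel, min_minor_count=min_minor_count)
    rng = np.random.default_rng(seed)
    keep = np.zeros(filtered.n_sites, dtype=bool)
    for c, want in real_counts.items():
        idx = np.flatnonzero(filtered.chrom == c)
        if len(idx) < want:
            raise ValueError(
                f"only {len(idx)} simulated SNPs on {c!r} after the MAF filter "
                f"but {want} are required; simulate a longer chromosome or "
                "more replicates"
            )
        chosen = rng.choice(idx, size=want, replace=False)
        keep[np.sort(chosen)] = True
    return filtered.take_sites(keep)


def calibrate_threshold(
    scan_fn: Callable[[VariantTable, SamplePanel], np.ndarray],
    sims: Sequence[tuple],
    q: float,
    statistic: str = "statistic",
    keep_values: bool = True,
) -> CalibrationResult:
    """Pool window values over simulated replicates; threshold = percentile.

    ``scan_fn(table, panel)`` must reproduce the real scan's windowing and
    filters and return the finite window values of one replicate.
    """
    pooled = []
    counts = []
    for item in sims:
        table, panel = (item.variants, item.panel) if hasattr(item, "variants") else item
        if hasattr(table, "variants"):  # a SyntheticCohort
            table = table.variants
        vals = np.asarray(scan_fn(table, panel), dtype=float)
        vals = vals[np.isfinite(vals)]
        pooled.append(vals)
        counts.append(len(vals))
    values = np.concatenate(pooled) if pooled else np.array([])
    if values.size == 0:
        raise ValueError("no window values pooled from simulations")
    thr = percentile_threshold(values, q)
    return CalibrationResult(
        statistic=statistic,
        q=q,
        threshold=thr,
        n_replicates=len(sims),
        per_replicate_counts=counts,
        pooled_values=values if keep_values else None,
    )
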
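"""Synthetic dog/wolf cohorts with planted truth for pipeline validation.

The real study inputs (43 village dogs, 10 wolves, 2 ancient dogs; windowed
read-depth tracks; gene/GO annotations) are emulated here so that every
downstream stage is testable without any sequence download:

* :func:`generate_cohort` draws neutral biallelic SNP genotypes under a
  coalescent-with-recombination demographic model (msprime) and then imposes
  selective sweeps by haplotype overwriting - inside each
  :class:`SweepSpec` interval the dog chromosomes are collapsed onto the
  per-site major haplotype, keeping a configurable residual fraction of
  sites untouched. Overwriting neutral genotypes gives exact truth labels
  without forward simulation.
* :func:`generate_ancient_samples` produces ancient-dog genotypes at the
  cohort's sites: carriers are homozygous for the swept haplotype, while
  non-carriers are set to an alternative haplotype preserved from the
  pre-sweep diversity.
* :func:`generate_depth_profiles` emits per-sample windowed read depth with
  a known GC bias and planted copy-number differences (:class:`CnvSpec`).
* :func:`generate_toy_annotation` builds non-overlapping gene models and a
  small rooted GO-like DAG with propagated annotations.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .demography import DemographicModel
from .genome_windows import make_windows
from .variant_io import AUTOSOME, SamplePanel, VariantTable, write_vcf

__all__ = [
    "SweepSpec",
    "CnvSpec",
    "SyntheticCohort",
    "DepthTrackSet",
    "generate_cohort",
    "generate_ancient_samples",
    "generate_depth_profiles",
    "generate_toy_annotation",
    "default_gc_bias",
]


@dataclass
class SweepSpec:
    """A planted selective sweep (truth label for recovery tests)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    mode: str = "fixed_haplotype"  # or "frequency_raise"
    population: str = "dog"
    residual: float = 0.0  # residual diversity fraction in [0, 1]
    ancient_carrier: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.residual <= 1:
            raise ValueError("residual diversity fraction must be in [0, 1]")
        if self.end <= self.start:
            raise ValueError("sweep interval must be non-empty")
        if self.mode not in {"fixed_haplotype", "frequency_raise"}:
            raise ValueError(f"unknown sweep mode {self.mode!r}")


@dataclass
class CnvSpec:
    """A planted copy-number difference: per-population CN distributions."""

    chrom: str
    start: int
    end: int
    cn_probs: dict  # population -> {copy_number: probability}

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNV interval must be non-empty")
        for pop, dist in self.cn_probs.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"CN probabilities for {pop!r} must sum to 1")
            if any((cn < 0 or int(cn) != cn) for cn in dist):
                raise ValueError("copy numbers must be non-negative integers")


@dataclass
class DepthTrackSet:
    """Windowed per-sample read depth with GC fractions and CN truth."""

    windows: pd.DataFrame  # chrom, start, end, gc
    depth: np.ndarray  # (n_windows, n_samples)
    samples: list[str]
    true_cn: np.ndarray  # (n_windows, n_samples)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gc = self.windows[["chrom", "start", "end", "gc"]]
        gc.to_csv(outdir / "gc.bed", sep="\t", header=False, index=False)
        for j, s in enumerate(self.samples):
            df = self.windows[["chrom", "start", "end"]].copy()
            df["depth"] = self.depth[:, j]
            df.to_csv(outdir / f"{s}.depth.bed", sep="\t", header=False, index=False)


@dataclass
class SyntheticCohort:
    """Generated genotypes plus the truth needed to score recovery."""

    variants: VariantTable  # modern samples only (dogs then wolves)
    panel: SamplePanel  # includes ancient rows
    ancient_haplotypes: np.ndarray  # (n_sites, 2 * n_ancient_pool), pre-policy
    sweeps: list[SweepSpec]
    presweep_haplotypes: dict = field(default_factory=dict)
    # sweep index -> (site_indices, modern-dog haplotype matrix before overwrite)
    cnvs: list[CnvSpec] = field(default_factory=list)
    depth: DepthTrackSet | None = None
    chrom_lengths: dict = field(default_factory=dict)

    @property
    def n_ancient_pool(self) -> int:
        return self.ancient_haplotypes.shape[1] // 2

    def swept_haplotype(self, sweep_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Site indices and per-site swept (dog major) allele for a sweep."""
        idx, _ = self.presweep_haplotypes[sweep_index]
        dogs = self.variants.sample_index(self.panel.dogs)
        dosage = self.variants.gt[np.ix_(idx, dogs)].astype(np.int64)
        nhap = 2 * len(dogs)
        maj = (dosage.sum(axis=1) * 2 > nhap).astype(np.int8)
        return idx, maj

    def write(self, outdir, ancient_gt: np.ndarray | None = None) -> None:
        """Emit VCF (modern + ancient samples), panel TSV and truth BEDs.

        ``ancient_gt`` overrides the raw held-out pool genotypes, e.g. with
        the output of :func:`generate_ancient_samples` after a carrier
        policy has been applied.
        """
        from dataclasses import replace
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if ancient_gt is None:
            ancient_gt = (
                self.ancient_haplotypes[:, 0::2] + self.ancient_haplotypes[:, 1::2]
            )
        anc_gt = np.asarray(ancient_gt, dtype=np.int8)
        anc = self.panel.ancients[: anc_gt.shape[1]]
        combined = replace(
            self.variants,
            gt=np.hstack([self.variants.gt, anc_gt]),
            samples=self.variants.samples + anc,
        )
        write_vcf(combined, outdir / "cohort.vcf", self.chrom_lengths)
        self.panel.to_tsv(outdir / "panel.tsv")
        pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "name": f"sweep_{i}:carrier={s.ancient_carrier}",
                }
                for i, s in enumerate(self.sweeps)
            ]
        ).to_csv(outdir / "truth_sweeps.bed", sep="\t", header=False, index=False)


def _validate_sweeps(sweeps, chrom_lengths) -> None:
    by_chrom: dict[str, list[SweepSpec]] = {}
    for s in sweeps:
        if s.chrom not in chrom_lengths:
            raise ValueError(f"sweep chromosome {s.chrom!r} not in chrom_lengths")
        if s.end > chrom_lengths[s.chrom] or s.start < 0:
            raise ValueError(f"sweep interval outside chromosome {s.chrom!r}")
        by_chrom.setdefault(s.chrom, []).append(s)
    for c, group in by_chrom.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping sweep intervals on {c!r}")


def _simulate_chrom(model, chrom, length, n_dogs, n_wolves, n_ancient, rng):
    dem = model.to_msprime()
    dog_pop = model.sample_population("dog")
    wolf_pop = model.sample_population("wolf")
    counts: dict[str, int] = {}
    counts[dog_pop] = counts.get(dog_pop, 0) + n_dogs + n_ancient
    counts[wolf_pop] = counts.get(wolf_pop, 0) + n_wolves
    sample_sets = [
        msprime.SampleSet(n, population=p, ploidy=2) for p, n in counts.items()
    ]
    seed_anc, seed_mut = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        sequence_length=length,
        recombination_rate=model.recombination_rate,
        random_seed=int(seed_anc),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=model.mutation_rate,
        model=msprime.BinaryMutationModel(),
        random_seed=int(seed_mut),
    )
    hap = ts.genotype_matrix().astype(np.int8)  # sites x haplotypes
    pos = ts.sites_position.astype(np.int64) + 1  # 1-based
    nhap = hap.shape[1]
    derived = hap.sum(axis=1)
    poly = (derived > 0) & (derived < nhap)
    return pos[poly], hap[poly]


def generate_cohort(
    model: DemographicModel,
    chrom_lengths: dict[str, int],
    sweeps: list[SweepSpec] = (),
    n_dogs: int = 43,
    n_wolves: int = 10,
    seed: int = 0,
    n_ancient: int = 2,
) -> SyntheticCohort:
    """Simulate a dog/wolf cohort and impose the requested sweeps.

    Returns genotypes for ``n_dogs + n_wolves`` modern diploids plus a pool
    of ``n_ancient`` held-out dog diploids (sampled from the dog lineage at
    time 0) whose haplotypes feed :func:`generate_ancient_samples`. Within
    each sweep interval, modern dog diversity is collapsed onto the per-site
    major haplotype except at a ``residual`` fraction of sites; outside
    sweeps genotypes are neutral draws under the model.
    """
    if n_dogs < 1 or n_wolves < 1:
        raise ValueError("need at least one dog and one wolf")
    if any(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    sweeps = list(sweeps)
    _validate_sweeps(sweeps, chrom_lengths)
    rng = np.random.default_rng(seed)

    all_pos, all_chrom, all_hap = [], [], []
    for chrom, length in chrom_lengths.items():
        pos, hap = _simulate_chrom(
            model, chrom, length, n_dogs, n_wolves, n_ancient, rng
        )
        all_pos.append(pos)
        all_chrom.append(np.full(len(pos), chrom, dtype=object))
        all_hap.append(hap)
    pos = np.concatenate(all_pos)
    chrom = np.concatenate(all_chrom)
    hap = np.vstack(all_hap) if all_hap else np.zeros((0, 0), dtype=np.int8)

    n_dog_hap = 2 * n_dogs
    n_anc_hap = 2 * n_ancient
    dog_hap = slice(0, n_dog_hap)
    anc_hap = slice(n_dog_hap, n_dog_hap + n_anc_hap)
    wolf_hap = slice(n_dog_hap + n_anc_hap, n_dog_hap + n_anc_hap + 2 * n_wolves)

    presweep: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, sw in enumerate(sweeps):
        idx = np.flatnonzero(
            (chrom == sw.chrom) & (pos - 1 >= sw.start) & (pos - 1 < sw.end)
        )
        presweep[i] = (idx, hap[np.ix_(idx, np.arange(n_dog_hap))].copy())
        if len(idx) == 0:
            continue
        dogs_block = hap[np.ix_(idx, np.arange(n_dog_hap))]
        maj = (dogs_block.sum(axis=1) * 2 > n_dog_hap).astype(np.int8)
        if sw.mode == "fixed_haplotype":
            overwrite = rng.random(len(idx)) >= sw.residual
            block = dogs_block.copy()
            block[overwrite, :] = maj[overwrite, None]
        else:  # frequency_raise: per chromosome copy, not per site
            flip = rng.random(dogs_block.shape) >= sw.residual
            block = np.where(flip, maj[:, None], dogs_block)
        hap[np.ix_(idx, np.arange(n_dog_hap))] = block

    dog_names = [f"dog{i:02d}" for i in range(n_dogs)]
    wolf_names = [f"wolf{i:02d}" for i in range(n_wolves)]
    anc_names = [f"ancient{i:02d}" for i in range(n_ancient)]
    sexes = lambda names: ["male" if i % 2 == 0 else "female" for i in range(len(names))]
    panel = SamplePanel(
        pd.DataFrame(
            {
                "sample": dog_names + wolf_names + anc_names,
                "population": ["dog"] * n_dogs
                + ["wolf"] * n_wolves
                + ["ancient"] * n_ancient,
                "sex": sexes(dog_names) + sexes(wolf_names) + sexes(anc_names),
            }
        )
    )

    def dosage(block_slice):
        block = hap[:, block_slice].astype(np.int8)
        return block[:, 0::2] + block[:, 1::2]

    gt = np.hstack([dosage(dog_hap), dosage(wolf_hap)]).astype(np.int8)
    n_sites = len(pos)
    table = VariantTable(
        chrom=chrom,
        pos=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        gt=gt,
        samples=dog_names + wolf_names,
        region_class=np.full(n_sites, AUTOSOME, dtype=np.int8),
        chrom_lengths=dict(chrom_lengths),
    )
    return SyntheticCohort(
        variants=table,
        panel=panel,
        ancient_haplotypes=hap[:, anc_hap].copy(),
        sweeps=sweeps,
        presweep_haplotypes=presweep,
        chrom_lengths=dict(chrom_lengths),
    )


def generate_ancient_samples(
    cohort: SyntheticCohort,
    n_ancient: int = 2,
    carrier_policy: dict[int, bool] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Ancient-dog diploid genotypes at the cohort's sites.

    ``carrier_policy`` maps sweep index -> whether the ancient samples carry
    the swept haplotype (default: each sweep's ``ancient_carrier`` flag).
    Carriers are homozygous for the swept haplotype across the interval;
    non-carriers are homozygous for an alternative haplotype drawn from the
    stored pre-sweep dog diversity.
    """
    if n_ancient > cohort.n_ancient_pool:
        raise ValueError("not enough held-out ancient haplotypes in the cohort")
    policy = {i: s.ancient_carrier for i, s in enumerate(cohort.sweeps)}
    if carrier_policy:
        policy.update(carrier_policy)
    if set(policy) != set(range(len(cohort.sweeps))):
        raise ValueError("carrier_policy must cover every sweep")
    rng = np.random.default_rng(seed)
    haps = cohort.ancient_haplotypes[:, : 2 * n_ancient].copy()
    for i, sw in enumerate(cohort.sweeps):
        idx, maj = cohort.swept_haplotype(i)
        if len(idx) == 0:
            continue
        if policy[i]:
            haps[idx, :] = maj[:, None]
        else:
            _, pre = cohort.presweep_haplotypes[i]
            differs = np.flatnonzero((pre != maj[:, None]).any(axis=0))
            if len(differs) == 0:
                raise ValueError(
                    f"sweep {i}: no stored pre-sweep haplotype differs from the "
                    "swept haplotype; cannot construct a non-carrier ancient"
                )
            # each ancient chromosome is a recombinant mosaic of the stored
            # pre-sweep haplotypes (an independent draw per site): a
            # non-carrier lineage separated from the swept population by
            # millennia carries ancestral diversity broken up by
            # recombination, not any single intact modern haplotype
            n_chrom = 2 * n_ancient
            picks = rng.integers(0, pre.shape[1], size=(len(idx), n_chrom))
            haps[idx[:, None], np.arange(n_chrom)[None, :]] = np.take_along_axis(
                pre, picks, axis=1
            )
    return (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)


def default_gc_bias(gc):
    """Smooth unimodal GC bias peaking at GC=0.45 with factors in [0.6, 1.1]."""
    gc = np.asarray(gc, dtype=float)
    return 0.6 + 0.5 * np.exp(-(((gc - 0.45) / 0.12) ** 2))


def generate_depth_profiles(
    panel: SamplePanel,
    chrom_lengths: dict[str, int],
    cnvs: list[CnvSpec] = (),
    window_size: int = 3000,
    mean_depth: float = 30.0,
    gc_bias_curve=default_gc_bias,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> DepthTrackSet:
    """Windowed read-depth tracks with planted copy-number differences.

    Per window and sample: depth = mean_depth * (CN / 2) * gc_bias(GC) *
    (1 + Gaussian noise). The true CN is 2 outside CNV intervals; windows
    overlapping a :class:`CnvSpec` get a per-sample CN drawn from that
    population's distribution (constant across the interval).
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    rng = np.random.default_rng(seed)
    windows = make_windows(chrom_lengths, window_size, window_size)
    gc = np.clip(rng.normal(0.42, 0.07, size=len(windows)), 0.25, 0.65)
    windows = windows.assign(gc=gc)
    samples = panel.df["sample"].tolist()
    pops = panel.df["population"].tolist()
    n_w, n_s = len(windows), len(samples)
    cn = np.full((n_w, n_s), 2.0)
    wchrom = windows["chrom"].to_numpy()
    wstart = windows["start"].to_numpy()
    wend = windows["end"].to_numpy()
    for cnv in cnvs:
        if cnv.chrom not in chrom_lengths:
            raise ValueError(f"CNV chromosome {cnv.chrom!r} not in chrom_lengths")
        hit = (wchrom == cnv.chrom) & (wstart < cnv.end) & (wend > cnv.start)
        for j, pop in enumerate(pops):
            dist = cnv.cn_probs.get(pop)
            if dist is None:
                continue
            values = np.array(sorted(dist), dtype=float)
            probs = np.array([dist[v] for v in sorted(dist)], dtype=float)
            cn[hit, j] = rng.choice(values, p=probs)
    bias = np.asarray(gc_bias_curve(gc), dtype=float)
    if np.any(bias <= 0):
        raise ValueError("GC bias factors must be positive")
    noise = rng.normal(0.0, noise_sd, size=(n_w, n_s)) if noise_sd > 0 else 0.0
    depth = np.maximum(mean_depth * (cn / 2.0) * bias[:, None] * (1.0 + noise), 0.0)
    return DepthTrackSet(windows=windows, depth=depth, samples=samples, true_cn=cn)


def generate_toy_annotation(
    chrom_lengths: dict[str, int],
    n_genes: int = 100,
    ontology_depth: int = 3,
    n_terms: int = 20,
    seed: int = 0,
):
    """Non-overlapping gene models plus a rooted GO-like DAG.

    Every non-root term has at least one parent; every gene is annotated to
    at least one term, and annotations propagate to all ancestors (done by
    the consumer, :class:`domestiscan.enrichment.Ontology`). Returns
    ``(genes, annotations, ontology)`` DataFrames (BED6-like / gene,term /
    child,parent).
    """
    if n_genes < 1 or n_terms < 1:
        raise ValueError("need at least one gene and one term")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    for i in range(n_genes - alloc.sum()):
        alloc[i % len(alloc)] += 1

    rows = []
    gid = 0
    for c, k in zip(chroms, alloc):
        if k == 0:
            continue
        glens = rng.integers(5_000, 30_001, size=k)
        slack = chrom_lengths[c] - int(glens.sum())
        if slack < 0:
            raise ValueError(f"genes cannot fit on {c!r} without overlap")
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        starts = cuts + np.concatenate([[0], np.cumsum(glens[:-1])])
        for s, l in zip(starts, glens):
            rows.append(
                {
                    "chrom": c,
                    "start": int(s),
                    "end": int(s + l),
                    "gene": f"gene{gid:04d}",
                    "score": 0,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            gid += 1
    genes = pd.DataFrame(rows)

    terms = [f"term{i:04d}" for i in range(n_terms)]
    levels = {terms[0]: 0}
    edges = []
    for i, t in enumerate(terms[1:], start=1):
        level = 1 + (i - 1) % max(ontology_depth, 1)
        levels[t] = level
        lower = [u for u in terms[:i] if levels[u] < level]
        n_par = min(len(lower), int(rng.integers(1, 3)))
        for p in rng.choice(len(lower), size=n_par, replace=False):
            edges.append({"child": t, "parent": lower[p]})
    ontology = pd.DataFrame(edges, columns=["child", "parent"])

    annot = []
    for g in genes["gene"]:
        k = int(rng.integers(1, min(3, n_terms) + 1))
        for t in rng.choice(n_terms, size=k, replace=False):
            annot.append({"gene": g, "term": terms[t]})
    annotations = pd.DataFrame(annot).drop_duplicates(ignore_index=True)
    return genes, annotations, ontology
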
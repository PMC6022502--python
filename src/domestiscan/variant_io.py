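"""VCF/panel input, site filtration, and per-population allele frequencies.

The scans operate on a cohort of village dogs and gray wolves (plus ancient
dog samples that enter only through the ΔHp filter). This module loads a
multi-sample VCF, applies the cohort site filters - biallelic SNPs only, no
missing genotypes, no SNPs within 5 bp of an indel present in the same VCF,
no X-nonPAR site at which any male is heterozygous - and produces the
per-population allele frequencies and dog major/minor allele counts that the
F_ST, H_P and XP-CLR statistics consume.

Genotypes are held as an int8 matrix of alternate-allele dosages (0, 1, 2;
-1 for missing during loading). Males on the X-nonPAR are hemizygous: their
calls are stored as homozygous dosages but contribute a single chromosome to
all allele counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# region classes
AUTOSOME, X_PAR, X_NONPAR = 0, 1, 2
_X_NAMES = {"X", "chrX"}

__all__ = [
    "SamplePanel",
    "VariantTable",
    "AlleleFrequencyTable",
    "load_variants",
    "write_vcf",
    "maf_filter",
    "allele_frequencies",
    "AUTOSOME",
    "X_PAR",
    "X_NONPAR",
]


@dataclass
class SamplePanel:
    """Sample sheet: id, population (dog / wolf / ancient) and sex."""

    df: pd.DataFrame  # columns: sample, population, sex

    def __post_init__(self) -> None:
        required = {"sample", "population", "sex"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.df["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in panel")
        bad = set(self.df["population"]) - {"dog", "wolf", "ancient"}
        if bad:
            raise ValueError(f"unknown populations in panel: {sorted(bad)}")

    def samples(self, population: str) -> list[str]:
        return self.df.loc[self.df["population"] == population, "sample"].tolist()

    @property
    def dogs(self) -> list[str]:
        return self.samples("dog")

    @property
    def wolves(self) -> list[str]:
        return self.samples("wolf")

    @property
    def ancients(self) -> list[str]:
        return self.samples("ancient")

    def sex_of(self, sample: str) -> str:
        row = self.df.loc[self.df["sample"] == sample, "sex"]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in panel")
        return row.iloc[0]

    @classmethod
    def from_tsv(cls, path) -> "SamplePanel":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class VariantTable:
    """Filtered biallelic SNP genotypes for a set of samples.

    ``gt`` is (n_sites, n_samples) int8 of ALT dosages. ``region_class``
    distinguishes autosomes from X-PAR and X-nonPAR, which changes how male
    chromosomes are counted.
    """

    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    samples: list[str]
    region_class: np.ndarray
    chrom_lengths: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in VariantTable") from None

    def take_sites(self, mask_or_idx) -> "VariantTable":
        return replace(
            self,
            chrom=self.chrom[mask_or_idx],
            pos=self.pos[mask_or_idx],
            ref=self.ref[mask_or_idx],
            alt=self.alt[mask_or_idx],
            gt=self.gt[mask_or_idx],
            region_class=self.region_class[mask_or_idx],
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.region_class, other.region_class)
        )


@dataclass
class AlleleFrequencyTable:
    """Per-site population frequencies and dog major/minor counts.

    ``p_dog``/``p_wolf`` are ALT frequencies over the population's
    chromosomes (males count one chromosome on the X-nonPAR). ``n_dog`` and
    ``n_wolf`` are the *individual* counts entering the Hudson estimator; on
    the X-nonPAR they are the effective chromosome count divided by two.
    ``n_maj``/``n_min`` are dog allele counts with the major/minor axis
    assigned within dogs (ties broken toward the reference allele).
    """

    chrom: np.ndarray
    pos: np.ndarray
    p_dog: np.ndarray
    p_wolf: np.ndarray
    n_dog: np.ndarray
    n_wolf: np.ndarray
    n_maj: np.ndarray
    n_min: np.ndarray
    major_is_alt: np.ndarray
    region_class: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "p_dog": self.p_dog,
                "p_wolf": self.p_wolf,
                "n_dog": self.n_dog,
                "n_wolf": self.n_wolf,
                "n_maj": self.n_maj,
                "n_min": self.n_min,
            }
        )


def _region_classes(chrom, pos, par_intervals) -> np.ndarray:
    rc = np.full(len(pos), AUTOSOME, dtype=np.int8)
    on_x = np.isin(chrom, list(_X_NAMES))
    if on_x.any():
        rc[on_x] = X_NONPAR
        if par_intervals:
            for start, end in par_intervals:
                in_par = on_x & (pos > start) & (pos <= end)
                rc[in_par] = X_PAR
        else:
            warnings.warn("X chromosome present but no PAR intervals supplied; "
                          "treating all X sites as non-PAR")
    return rc


def load_variants(vcf_path, panel: SamplePanel, par_intervals=None) -> VariantTable:
    """Load and filter biallelic SNPs from a VCF.

    Drops sites with any missing genotype, non-biallelic/non-SNP records,
    SNPs within 5 bp of an indel present in the same VCF, and X-nonPAR sites
    where any male is heterozygous. ``par_intervals`` is a list of 0-based
    half-open (start, end) intervals on the X.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    panel_samples = set(panel.df["sample"])
    missing = [s for s in vcf_samples if s not in panel_samples]
    if missing:
        raise ValueError(f"VCF samples missing from panel: {missing}")

    male = np.array(
        [panel.sex_of(s) == "male" for s in vcf_samples], dtype=bool
    )

    chroms, poss, refs, alts, gts = [], [], [], [], []
    indels: list[tuple[str, int, int]] = []
    chrom_lengths = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        chrom_lengths[name] = length

    for i, var in enumerate(vcf):
        if var.is_indel:
            end = var.POS + max(len(var.REF), 1) - 1
            indels.append((var.CHROM, var.POS, end))
            continue
        if not var.is_snp or len(var.ALT) != 1:
            continue  # triallelic or otherwise non-biallelic-SNP
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        if (g == 3).any():
            continue  # missing genotype in some sample
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gts.append(g)

    chrom = np.array(chroms, dtype=object)
    pos = np.array(poss, dtype=np.int64)
    ref = np.array(refs, dtype=object)
    alt = np.array(alts, dtype=object)
    gt = (
        np.vstack(gts).astype(np.int8)
        if gts
        else np.zeros((0, len(vcf_samples)), dtype=np.int8)
    )

    # SNPs within 5 bp of an indel in the same VCF
    if indels:
        keep = np.ones(len(pos), dtype=bool)
        for ic, istart, iend in indels:
            hit = (chrom == ic) & (pos >= istart - 5) & (pos <= iend + 5)
            keep &= ~hit
        chrom, pos, ref, alt, gt = chrom[keep], pos[keep], ref[keep], alt[keep], gt[keep]
    else:
        logger.warning("no indel records in VCF; indel-proximity filter is a no-op")

    rc = _region_classes(chrom, pos, par_intervals)

    # X-nonPAR sites with a male heterozygote are unreliable calls
    if male.any():
        het_male = (gt[:, male] == 1).any(axis=1)
        drop = (rc == X_NONPAR) & het_male
        if drop.any():
            keep = ~drop
            chrom, pos, ref, alt, gt, rc = (
                chrom[keep], pos[keep], ref[keep], alt[keep], gt[keep], rc[keep]
            )

    return VariantTable(chrom, pos, ref, alt, gt, vcf_samples, rc, chrom_lengths)


def write_vcf(table: VariantTable, path, chrom_lengths=None) -> None:
    """Write the table as a minimal VCF 4.2 with GT fields only."""
    lengths = dict(table.chrom_lengths)
    if chrom_lengths:
        lengths.update(chrom_lengths)
    order = list(dict.fromkeys(table.chrom.tolist()))
    gt_str = np.array(["0/0", "0/1", "1/1", "./."], dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in order:
            if c in lengths:
                fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        gt = table.gt
        for i in range(table.n_sites):
            row = gt_str[np.where(gt[i] < 0, 3, gt[i])]
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t.\tGT\t" + "\t".join(row) + "\n"
            )


def _chromosome_weights(table: VariantTable, panel: SamplePanel, names) -> np.ndarray:
    """Per (site, sample) chromosome count: 2, except male X-nonPAR -> 1."""
    idx = table.sample_index(names)
    male = np.array([panel.sex_of(s) == "male" for s in names], dtype=bool)
    w = np.full((table.n_sites, len(names)), 2, dtype=np.int64)
    nonpar = table.region_class == X_NONPAR
    if nonpar.any() and male.any():
        w[np.ix_(nonpar, male)] = 1
    return w, idx


def _pop_counts(table: VariantTable, panel: SamplePanel, names):
    """ALT allele count and chromosome total per site for a sample set."""
    w, idx = _chromosome_weights(table, panel, names)
    gt = table.gt[:, idx].astype(np.int64)
    # dosage 2 on one male X chromosome contributes 1 ALT allele
    alt = np.where(w == 1, gt // 2, gt).sum(axis=1)
    total = w.sum(axis=1)
    return alt, total


def maf_mask(table: VariantTable, panel: SamplePanel, min_minor_count: int = 3) -> np.ndarray:
    """Boolean mask of sites passing the minor-allele-count filter."""
    modern = [s for s in panel.dogs + panel.wolves if s in table.samples]
    alt, total = _pop_counts(table, panel, modern)
    if np.any(alt > total):
        raise ValueError("allele count exceeds chromosome total")
    minor = np.minimum(alt, total - alt)
    return minor >= min_minor_count


def maf_filter(table: VariantTable, panel: SamplePanel, min_minor_count: int = 3) -> VariantTable:
    """Drop sites whose minor-allele count over all modern samples is below
    ``min_minor_count`` (strict <; the cohort default 3 of 106 alleles is a
    frequency cutoff of 0.028). Ancient samples do not enter the count."""
    return table.take_sites(maf_mask(table, panel, min_minor_count))


def allele_frequencies(table: VariantTable, panel: SamplePanel) -> AlleleFrequencyTable:
    """Per-site dog and wolf ALT frequencies plus dog major/minor counts.

    Major/minor axes are assigned within dogs; at a 50/50 tie the reference
    allele is called major. ``n_dog``/``n_wolf`` are individual counts; on
    the X-nonPAR they equal the effective chromosome count divided by two so
    the Hudson formula remains applicable.
    """
    dogs, wolves = panel.dogs, panel.wolves
    if not dogs or not wolves:
        raise ValueError("both dog and wolf populations must be non-empty")
    alt_d, tot_d = _pop_counts(table, panel, dogs)
    alt_w, tot_w = _pop_counts(table, panel, wolves)
    with np.errstate(invalid="ignore"):
        p_dog = alt_d / tot_d
        p_wolf = alt_w / tot_w
    major_is_alt = alt_d * 2 > tot_d  # strict majority; tie -> REF is major
    n_maj = np.where(major_is_alt, alt_d, tot_d - alt_d)
    n_min = tot_d - n_maj
    return AlleleFrequencyTable(
        chrom=table.chrom,
        pos=table.pos,
        p_dog=p_dog,
        p_wolf=p_wolf,
        n_dog=tot_d / 2.0,
        n_wolf=tot_w / 2.0,
        n_maj=n_maj,
        n_min=n_min,
        major_is_alt=major_is_alt,
        region_class=table.region_class.copy(),
    )


def read_par_bed(path) -> list[tuple[int, int]]:
    """PAR intervals from a BED file (coordinates on the X)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return list(zip(df["start"].astype(int), df["end"].astype(int)))
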
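"""Pooled heterozygosity (H_P) windows and the ancient-dog ΔH_P filter.

H_P summarises dog diversity in a window from pooled allele counts:

    H_P = 2 * Σn_MAJ * Σn_MIN / (Σn_MAJ + Σn_MIN)^2

where Σn_MAJ and Σn_MIN are the sums over the window's sites of the dog
major- and minor-allele counts. A completed selective sweep drives H_P
toward 0. ΔH_P is the change in H_P when the chromosomes of ancient dog
samples are added to the pool, holding each site's major/minor axis fixed
at its modern-dog assignment: ancient dogs that carry the putatively swept
(major) haplotype leave H_P unchanged or lower it (ΔH_P <= 0), whereas
ancient dogs carrying a different haplotype add minor alleles and raise it.
Filtering candidate windows on ΔH_P therefore removes sweeps that postdate
the ancient samples or are absent from their lineage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_windows import assign_sites
from .variant_io import AlleleFrequencyTable

__all__ = ["pooled_hp", "window_hp", "delta_hp", "apply_hp_filters"]


def pooled_hp(sum_nmaj, sum_nmin):
    """H_P from pooled major/minor counts (vectorised). NaN when empty."""
    sum_nmaj = np.asarray(sum_nmaj, dtype=float)
    sum_nmin = np.asarray(sum_nmin, dtype=float)
    tot = sum_nmaj + sum_nmin
    with np.errstate(divide="ignore", invalid="ignore"):
        hp = np.where(tot > 0, 2.0 * sum_nmaj * sum_nmin / tot**2, np.nan)
    return float(hp) if hp.ndim == 0 else hp


def _ancient_added_counts(af: AlleleFrequencyTable, ancient_gt: np.ndarray):
    """Major/minor allele counts contributed by ancient diploid genotypes.

    ``ancient_gt``: (n_sites, n_ancient) ALT dosages, -1 for missing calls
    (missing samples are skipped per site). The major/minor axis per site is
    the modern-dog assignment frozen in ``af``.
    """
    if ancient_gt.ndim == 1:
        ancient_gt = ancient_gt[:, None]
    if ancient_gt.shape[0] != af.n_sites:
        raise ValueError("ancient genotypes do not match the site table")
    present = ancient_gt >= 0
    alt_added = np.where(present, ancient_gt, 0).sum(axis=1)
    chrom_added = 2 * present.sum(axis=1)
    maj_added = np.where(af.major_is_alt, alt_added, chrom_added - alt_added)
    min_added = chrom_added - maj_added
    return maj_added, min_added


def window_hp(
    af: AlleleFrequencyTable,
    windows: pd.DataFrame,
    ancient_gt: np.ndarray | None = None,
) -> pd.DataFrame:
    """Window H_P (and ΔH_P when ancient genotypes are supplied).

    Adds ``sum_nmaj``, ``sum_nmin``, ``hp`` and, with ancient samples,
    ``hp_with_ancient`` and ``delta_hp`` columns. Windows without sites get
    NaN values.
    """
    out = windows.copy()
    lo, hi = assign_sites(windows, af.chrom, af.pos)
    cmaj = np.concatenate([[0], np.cumsum(af.n_maj)])
    cmin = np.concatenate([[0], np.cumsum(af.n_min)])
    smaj = (cmaj[hi] - cmaj[lo]).astype(float)
    smin = (cmin[hi] - cmin[lo]).astype(float)
    out["n_sites"] = hi - lo
    out["sum_nmaj"] = smaj
    out["sum_nmin"] = smin
    out["hp"] = pooled_hp(smaj, smin)
    if ancient_gt is not None:
        maj_added, min_added = _ancient_added_counts(af, np.asarray(ancient_gt))
        camaj = np.concatenate([[0], np.cumsum(af.n_maj + maj_added)])
        camin = np.concatenate([[0], np.cumsum(af.n_min + min_added)])
        hp_with = pooled_hp(
            (camaj[hi] - camaj[lo]).astype(float),
            (camin[hi] - camin[lo]).astype(float),
        )
        out["hp_with_ancient"] = hp_with
        out["delta_hp"] = hp_with - out["hp"]
    return out


def delta_hp(af: AlleleFrequencyTable, window: tuple, ancient_gt: np.ndarray) -> float:
    """ΔH_P for a single (chrom, start, end) window."""
    win = pd.DataFrame({"chrom": [window[0]], "start": [window[1]], "end": [window[2]]})
    res = window_hp(af, win, ancient_gt=ancient_gt)
    return float(res["delta_hp"].iloc[0])


def apply_hp_filters(
    windows: pd.DataFrame, hp_threshold: float, dhp_threshold: float
) -> pd.DataFrame:
    """Flag windows by the two heterozygosity filters.

    A window passes iff ``hp < hp_threshold`` (low diversity, consistent
    with a completed sweep) AND ``delta_hp <= dhp_threshold`` (ancient dogs
    do not add diversity beyond the genome-wide threshold, i.e. they carry
    the swept haplotype). Thresholds come from neutral-simulation and
    genome-wide ΔH_P percentiles respectively.
    """
    if hp_threshold is None or dhp_threshold is None:
        raise ValueError("hp and ΔHp thresholds are both required")
    out = windows.copy()
    hp = out["hp"].to_numpy(dtype=float)
    dhp = out["delta_hp"].to_numpy(dtype=float)
    out["pass_hp"] = np.isfinite(hp) & (hp < hp_threshold)
    out["pass_dhp"] = np.isfinite(dhp) & (dhp <= dhp_threshold)
    out["pass_hp_filters"] = out["pass_hp"] & out["pass_dhp"]
    return out
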
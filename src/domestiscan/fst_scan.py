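"""Hudson-estimator F_ST: per-site values and windowed ratio of averages.

F_ST measures allele-frequency differentiation between village dogs and
wolves. Per site, with dog ALT frequency p1 over n1 individuals and wolf
ALT frequency p2 over n2 individuals, the Hudson estimator is

    numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)
    F_ST        = numerator / denominator

(the sample-size terms correct for the finite cohort; the estimator reaches
1 only at a fixed difference). Window values are the ratio of averages:
mean numerator over mean denominator across the SNPs in a 200-kb sliding
window (50-kb step), requiring at least 10 SNPs per window. Sites at which
both populations are fixed for the same allele have an undefined estimator
(denominator 0) and are excluded.

Two significance modes exist: the empirical outlier mode (Z-transformed
window values, Z >= 5 on autosomes and X-PAR, Z >= 3 on the X-nonPAR) and
the simulation-calibrated mode (window value strictly greater than a
threshold calibrated as a percentile of neutral-simulation window values).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_windows import assign_sites, make_windows, merge_regions, z_transform
from .variant_io import AlleleFrequencyTable, X_NONPAR

__all__ = [
    "hudson_fst_site",
    "fst_sites",
    "windowed_fst",
    "fst_outlier_scan",
]


def hudson_fst_site(p1, n1, p2, n2):
    """Hudson F_ST components for one site (vectorised over arrays).

    ``n1``/``n2`` are the sample sizes whose finite-sample correction terms
    p(1-p)/(n-1) remove the sampling contribution to (p1-p2)^2; for an
    unbiased estimator they must be the numbers of sampled *chromosomes*
    (haploid sample sizes - see :func:`fst_sites`), since Var(p_hat) =
    p(1-p)/n_chromosomes. Returns ``(numerator, denominator, fst)``;
    ``fst`` is NaN where the denominator is 0 (both populations fixed for
    the same allele).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 individuals per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    if fst.ndim == 0:
        return float(num), float(den), float(fst)
    return num, den, fst


def fst_sites(af: AlleleFrequencyTable) -> pd.DataFrame:
    """Per-site F_ST table; non-computable sites (denominator 0) excluded.

    The correction terms use haploid sample sizes (2 x the individual counts
    carried by the frequency table; X-nonPAR males already count one
    chromosome there): with per-individual counts the estimator would be
    biased to about -1/n under no differentiation instead of centring on 0.
    """
    num, den, fst = hudson_fst_site(
        af.p_dog, 2.0 * af.n_dog, af.p_wolf, 2.0 * af.n_wolf
    )
    keep = den > 0
    return pd.DataFrame(
        {
            "chrom": af.chrom[keep],
            "pos": af.pos[keep],
            "num": np.atleast_1d(num)[keep],
            "den": np.atleast_1d(den)[keep],
            "fst": np.atleast_1d(fst)[keep],
            "region_class": af.region_class[keep],
        }
    )


def windowed_fst(
    sites: pd.DataFrame, windows: pd.DataFrame, min_snps: int = 10
) -> pd.DataFrame:
    """Ratio-of-averages F_ST per window.

    Window value = mean(numerators) / mean(denominators) over the SNPs in
    the window; windows with fewer than ``min_snps`` SNPs are flagged
    unusable (``value`` NaN, ``usable`` False).
    """
    out = windows.copy()
    lo, hi = assign_sites(windows, sites["chrom"].to_numpy(), sites["pos"].to_numpy())
    cnum = np.concatenate([[0.0], np.cumsum(sites["num"].to_numpy())])
    cden = np.concatenate([[0.0], np.cumsum(sites["den"].to_numpy())])
    crc = np.concatenate([[0], np.cumsum((sites["region_class"].to_numpy() == X_NONPAR))])
    support = hi - lo
    snum = cnum[hi] - cnum[lo]
    sden = cden[hi] - cden[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(sden > 0, snum / sden, np.nan)
    usable = support >= min_snps
    nonpar_sites = crc[hi] - crc[lo]
    out["support"] = support
    out["value"] = np.where(usable, value, np.nan)
    out["usable"] = usable & np.isfinite(value)
    # a window is X-nonPAR if most of its sites are
    out["partition"] = np.where(nonpar_sites * 2 > np.maximum(support, 1),
                                "x_nonpar", "auto_par")
    return out


def fst_outlier_scan(
    windows: pd.DataFrame,
    mode: str = "empirical",
    z_auto: float = 5.0,
    z_nonpar: float = 3.0,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Select significant windows and merge overlapping ones into regions.

    ``empirical``: keep Z >= 5 (autosome / X-PAR) or Z >= 3 (X-nonPAR) -
    windows must carry a ``zscore`` column (see :func:`z_transform`).
    ``calibrated``: keep window value strictly greater than ``threshold``.
    """
    usable = windows[windows["usable"]].copy() if "usable" in windows else windows.copy()
    if mode == "empirical":
        if "zscore" not in usable.columns:
            usable = z_transform(usable)
        zcut = np.where(usable["partition"] == "x_nonpar", z_nonpar, z_auto)
        passing = usable[usable["zscore"] >= zcut]
    elif mode == "calibrated":
        if threshold is None:
            raise ValueError("calibrated mode requires a threshold")
        passing = usable[usable["value"] > threshold]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return merge_regions(passing, max_gap=0, value_col="value", source="fst")


def fst_scan(af: AlleleFrequencyTable, chrom_lengths, size=200_000, step=50_000,
             min_snps=10) -> pd.DataFrame:
    """Convenience: windows + per-site F_ST + windowed ratio of averages."""
    windows = make_windows(chrom_lengths, size, step)
    return windowed_fst(fst_sites(af), windows, min_snps=min_snps)
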
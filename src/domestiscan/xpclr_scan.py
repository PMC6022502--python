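"""XP-CLR: cross-population composite-likelihood selection scan.

XP-CLR (Chen, Patterson & Reich 2010, Genome Res 20:393) detects selective
sweeps in an object population (here village dogs) from multilocus allele
frequency differentiation against a reference population (wolves). This is
an independent re-implementation of that framework with the runtime
parameters used throughout this package (2-kb score grid, 50-kb SNP window,
25-kb/10-kb window averaging, >= 5 grid points per window):

* Neutral model: the dog frequency at a SNP is the wolf frequency plus
  Brownian drift, p1 ~ N(p2, omega * p2(1-p2)) truncated to [0, 1] with the
  tail mass collected into atoms at the boundaries. The drift variance
  omega is estimated genome-wide by method of moments from the dog-wolf
  frequency differences (it absorbs sampling noise in both cohorts).
* Selection model: a sweep centred at the grid point with scale parameter
  ``s`` (in Morgans) lets a lineage at genetic distance r escape with
  probability e = 1 - exp(-r/s). A neutral allele linked to the beneficial
  background (probability p2) is dragged to 1 - e + e*p1; an unlinked one
  is pushed to e*p1. The dog frequency is then a two-component truncated
  normal mixture whose drift variance scales with e^2.
* Score: per grid point, 2 * (max over the s grid of the composite
  log-likelihood - the neutral composite log-likelihood), using all SNPs
  within half a SNP window of the grid point. The grid of s values always
  includes 0 (where e = 1 and the mixture collapses exactly onto the
  neutral model), so scores are non-negative by construction.

Genetic distances come from a genetic map table (linear interpolation,
terminal-rate extrapolation) or a uniform rate fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .genome_windows import make_windows, merge_regions
from .variant_io import AlleleFrequencyTable

__all__ = [
    "GeneticMap",
    "XpclrConfig",
    "genetic_distances",
    "estimate_omega",
    "xpclr_score_grid",
    "average_grid_windows",
    "xpclr_candidates",
]

_LOG_FLOOR = 1e-300


@dataclass
class GeneticMap:
    """Physical -> genetic distance, from anchors or a uniform rate.

    ``table``: DataFrame with columns chrom, pos (bp), morgans (cumulative),
    non-decreasing in pos. Without a table, a uniform ``rate`` in Morgans
    per bp applies (default 1e-8 = 1 cM/Mb).
    """

    table: pd.DataFrame | None = None
    rate: float = 1e-8

    @classmethod
    def from_tsv(cls, path, rate: float = 1e-8) -> "GeneticMap":
        """Read a genetic map table: columns chrom, pos, cM (centimorgans,
        cumulative). ``rate`` remains the fallback for unlisted chromosomes."""
        df = pd.read_csv(path, sep="\t")
        if not {"chrom", "pos", "cM"} <= set(df.columns):
            raise ValueError("genetic map TSV needs chrom, pos, cM columns")
        table = df.assign(morgans=df["cM"] / 100.0)[["chrom", "pos", "morgans"]]
        return cls(table=table, rate=rate)

    def distances(self, chrom: str, positions) -> np.ndarray:
        positions = np.asarray(positions, dtype=float)
        if self.table is None:
            return positions * self.rate
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            return positions * self.rate
        pos = sub["pos"].to_numpy(dtype=float)
        mor = sub["morgans"].to_numpy(dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("genetic map positions must be strictly increasing")
        if np.any(np.diff(mor) < 0):
            raise ValueError("genetic map must be non-decreasing")
        if len(pos) == 1:
            return mor[0] + (positions - pos[0]) * self.rate
        # linear interpolation; extrapolate with the terminal segment rates
        out = np.interp(positions, pos, mor)
        lo_rate = (mor[1] - mor[0]) / (pos[1] - pos[0])
        hi_rate = (mor[-1] - mor[-2]) / (pos[-1] - pos[-2])
        below = positions < pos[0]
        above = positions > pos[-1]
        out[below] = mor[0] + (positions[below] - pos[0]) * lo_rate
        out[above] = mor[-1] + (positions[above] - pos[-1]) * hi_rate
        return out


def genetic_distances(positions, gmap: GeneticMap, chrom: str = "1") -> np.ndarray:
    """Cumulative genetic position (Morgans) of each physical position."""
    return gmap.distances(chrom, positions)


@dataclass
class XpclrConfig:
    """Runtime parameters of the scan.

    ``sel_grid`` are sweep scale parameters in Morgans (0 = neutral, always
    included); the upper end of the default grid corresponds to sweeps whose
    hitchhiking footprint spans the whole 50-kb SNP window.
    """

    grid_spacing: int = 2_000
    snp_window: int = 50_000
    sel_grid: tuple = (0.0, 2e-5, 1e-4, 5e-4, 2e-3, 1e-2)
    omega: float | None = None  # estimated from data when None
    max_snps: int | None = None  # optional per-window downsampling

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0 or self.snp_window <= 0:
            raise ValueError("grid spacing and SNP window must be positive")
        if 0.0 not in self.sel_grid:
            self.sel_grid = (0.0,) + tuple(self.sel_grid)


def estimate_omega(af: AlleleFrequencyTable, min_sites: int = 100) -> float:
    """Genome-wide drift variance of dog given wolf frequencies.

    Method of moments: omega = mean[(p1 - p2)^2 / (p2c (1 - p2c))] over
    polymorphic sites with the wolf frequency clamped off the boundaries.
    Includes sampling noise of both cohorts, which is what the neutral
    likelihood needs.
    """
    p1 = np.asarray(af.p_dog, dtype=float)
    n2 = np.asarray(af.n_wolf, dtype=float)
    p2 = _clamp_ref(np.asarray(af.p_wolf, dtype=float), n2)
    ratio = (p1 - p2) ** 2 / (p2 * (1 - p2))
    ratio = ratio[np.isfinite(ratio)]
    if ratio.size < min_sites:
        raise ValueError(f"need >= {min_sites} sites to estimate omega")
    return float(ratio.mean())


def _clamp_ref(p2: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Clamp reference frequencies off 0/1 to keep likelihoods finite."""
    eps = 1.0 / (2.0 * n2 + 1.0)
    return np.clip(p2, eps, 1.0 - eps)


def _mix_loglik(p1, p2, e, var_drift, var_samp):
    """Log-likelihood of observed dog frequencies under the sweep mixture.

    All arguments are broadcastable arrays. ``e`` is the escape probability
    (e = 1 recovers the neutral model exactly). The drift variance scales
    with e^2 (drift precedes the sweep, and hitchhiking compresses it) while
    the sampling variance ``var_samp`` does not - the cohort's binomial
    sampling noise survives any sweep, and without this floor an observed
    fixation would never favour the sweep model. Boundary observations
    (p1 = 0 or 1) use the truncated-normal atom mass.
    """
    mu_hitch = (1.0 - e) + e * p2
    mu_other = e * p2
    sd = np.sqrt(np.maximum(e**2 * var_drift + var_samp, 1e-12))

    def comp(mu):
        z_lo = (0.0 - mu) / sd
        z_hi = (1.0 - mu) / sd
        at0 = ndtr(z_lo)
        at1 = 1.0 - ndtr(z_hi)
        zz = (p1 - mu) / sd
        pdf = np.exp(-0.5 * zz**2) / (sd * np.sqrt(2.0 * np.pi))
        return np.where(p1 <= 0.0, at0, np.where(p1 >= 1.0, at1, pdf))

    lik = p2 * comp(mu_hitch) + (1.0 - p2) * comp(mu_other)
    return np.log(np.maximum(lik, _LOG_FLOOR))


def xpclr_score_grid(
    af: AlleleFrequencyTable,
    gmap: GeneticMap | None = None,
    config: XpclrConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Composite-likelihood-ratio score at grid points every 2 kb.

    Returns a DataFrame with chrom, gpos (grid point, bp), score, n_snps and
    an ``ok`` flag (False where no SNP lies within the window). Scores are
    2 * [max_s CLL(s) - CLL(0)] >= 0.
    """
    gmap = gmap or GeneticMap()
    config = config or XpclrConfig()
    omega = config.omega if config.omega is not None else estimate_omega(af)
    half = config.snp_window // 2
    sel = np.array([s for s in config.sel_grid if s > 0], dtype=float)

    frames = []
    chrom_order = list(dict.fromkeys(af.chrom.tolist()))
    for c in chrom_order:
        mask = af.chrom == c
        pos = af.pos[mask].astype(np.int64)
        p1 = np.asarray(af.p_dog[mask], dtype=float)
        n2 = np.asarray(af.n_wolf[mask], dtype=float)
        p2 = _clamp_ref(np.asarray(af.p_wolf[mask], dtype=float), n2)
        length = (
            chrom_lengths[c]
            if chrom_lengths and c in chrom_lengths
            else int(pos.max()) if len(pos) else 0
        )
        gpos = np.arange(0, length + 1, config.grid_spacing, dtype=np.int64)
        if len(gpos) == 0 or len(pos) == 0:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "gpos": gpos,
                        "score": np.nan,
                        "n_snps": 0,
                        "ok": False,
                    }
                )
            )
            continue
        n1 = np.asarray(af.n_dog[mask], dtype=float)
        d_snp = gmap.distances(c, pos)
        d_grid = gmap.distances(c, gpos)

        lo = np.searchsorted(pos, gpos - half, side="left")
        hi = np.searchsorted(pos, gpos + half, side="right")
        counts = hi - lo
        if config.max_snps is not None:
            counts = np.minimum(counts, config.max_snps)
            hi = lo + counts
        total = int(counts.sum())
        grid_ids = np.repeat(np.arange(len(gpos)), counts)
        # flat SNP indices for each grid point's range
        snp_ids = np.concatenate(
            [np.arange(l, h) for l, h in zip(lo, hi)] or [np.array([], dtype=int)]
        )

        # split omega into sampling noise (does not shrink under a sweep)
        # and genuine drift (does): omega_samp ~ 1/2n1 + 1/2n2 on the
        # p2(1-p2) scale
        omega_samp = 1.0 / (2.0 * n1) + 1.0 / (2.0 * n2)
        omega_drift = np.maximum(omega - omega_samp, 0.05 * omega)
        var_drift = omega_drift * p2 * (1.0 - p2)
        var_samp = omega_samp * p2 * (1.0 - p2)
        ll0_site = _mix_loglik(p1, p2, np.ones_like(p1), var_drift, var_samp)
        ll0 = np.bincount(grid_ids, weights=ll0_site[snp_ids], minlength=len(gpos))

        r = np.abs(d_snp[snp_ids] - d_grid[grid_ids])
        best = ll0.copy()
        for s in sel:
            e = 1.0 - np.exp(-r / s)
            ll = _mix_loglik(
                p1[snp_ids], p2[snp_ids], e, var_drift[snp_ids], var_samp[snp_ids]
            )
            lls = np.bincount(grid_ids, weights=ll, minlength=len(gpos))
            np.maximum(best, lls, out=best)
        score = 2.0 * (best - ll0)
        ok = counts > 0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "gpos": gpos,
                    "score": np.where(ok, score, np.nan),
                    "n_snps": counts,
                    "ok": ok,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def average_grid_windows(
    grid: pd.DataFrame,
    chrom_lengths: dict[str, int],
    win: int = 25_000,
    step: int = 10_000,
    min_grids: int = 5,
) -> pd.DataFrame:
    """Mean XP-CLR score of passing grid points in 25-kb sliding windows.

    Windows containing fewer than ``min_grids`` scored grid points are
    removed (the ``usable`` flag is False and the value NaN).
    """
    windows = make_windows(chrom_lengths, win, step)
    okg = grid[grid["ok"]].sort_values(["chrom", "gpos"], kind="mergesort")
    support = np.zeros(len(windows), dtype=np.int64)
    value = np.full(len(windows), np.nan)
    for c in windows["chrom"].unique():
        g = okg[okg["chrom"] == c]
        gp = g["gpos"].to_numpy()
        sc = g["score"].to_numpy(dtype=float)
        csc = np.concatenate([[0.0], np.cumsum(sc)])
        wmask = (windows["chrom"] == c).to_numpy()
        ws = windows.loc[wmask, "start"].to_numpy()
        we = windows.loc[wmask, "end"].to_numpy()
        lo = np.searchsorted(gp, ws, side="left")
        hi = np.searchsorted(gp, we, side="left")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(n > 0, (csc[hi] - csc[lo]) / np.maximum(n, 1), np.nan)
        support[wmask] = n
        value[wmask] = v
    out = windows.assign(support=support, value=value)
    out["usable"] = (support >= min_grids) & np.isfinite(value)
    out.loc[~out["usable"], "value"] = np.nan
    return out


def xpclr_candidates(
    windows: pd.DataFrame,
    threshold: float,
    hp_threshold: float | None = None,
    dhp_threshold: float | None = None,
    max_gap: int = 50_000,
) -> pd.DataFrame:
    """Final XP-CLR candidate regions.

    Keeps usable windows with score strictly above the calibrated threshold
    and - when heterozygosity columns are present - hp < hp_threshold and
    ΔHp <= dhp_threshold; passing windows within ``max_gap`` bp of each
    other merge into one region.
    """
    if threshold is None:
        raise ValueError("calibrated XP-CLR threshold is required")
    df = windows[windows["usable"]] if "usable" in windows else windows
    passing = df["value"] > threshold
    if "hp" in df.columns:
        if hp_threshold is None or dhp_threshold is None:
            raise ValueError("hp/ΔHp thresholds required when filtering on them")
        passing &= df["hp"] < hp_threshold
        passing &= df["delta_hp"] <= dhp_threshold
    return merge_regions(df[passing], max_gap=max_gap, value_col="value",
                         source="xpclr")
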
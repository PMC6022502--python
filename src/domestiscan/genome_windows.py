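"""Shared genomic-window machinery for all scans.

Every scan in this package (F_ST, pooled heterozygosity, XP-CLR window
averaging, V_ST) operates on sliding or tiled windows, normalises window
statistics by Z-transformation within a chromosome partition, thresholds them
against a percentile, and merges passing windows into candidate regions.
Those four primitives live here so each scan applies identical conventions.

Windows are 0-based half-open intervals carried in pandas DataFrames with at
least ``chrom``, ``start`` and ``end`` columns. Only full-size windows are
emitted: a terminal fragment shorter than ``size`` is dropped so that window
statistics stay comparable across the genome.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "make_windows",
    "assign_sites",
    "z_transform",
    "percentile_threshold",
    "merge_regions",
]


def make_windows(chrom_lengths: Mapping[str, int], size: int, step: int) -> pd.DataFrame:
    """Tile each chromosome with sliding windows of ``size`` every ``step`` bp.

    Window starts are 0, step, 2*step, ...; a window is kept only if
    ``start + size <= chromosome length``.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if size < step:
        raise ValueError("window size must be >= step")
    chroms, starts = [], []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        n = (length - size) // step + 1 if length >= size else 0
        s = np.arange(n, dtype=np.int64) * step
        starts.append(s)
        chroms.extend([chrom] * n)
    start = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    return pd.DataFrame(
        {"chrom": pd.array(chroms, dtype=object), "start": start, "end": start + size}
    )


def assign_sites(
    windows: pd.DataFrame, chrom: np.ndarray, pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Index ranges of sites falling in each window.

    ``pos`` is 1-based (VCF convention) and must be sorted within each
    chromosome. Returns ``(lo, hi)`` such that sites ``lo[i]:hi[i]`` (indices
    into the site arrays) lie inside window ``i``'s half-open interval.
    """
    lo = np.zeros(len(windows), dtype=np.int64)
    hi = np.zeros(len(windows), dtype=np.int64)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    for c in windows["chrom"].unique():
        sel = np.flatnonzero(chrom == c)
        cpos = pos[sel]
        if len(sel) and np.any(np.diff(cpos) < 0):
            raise ValueError(f"site positions on {c!r} are not sorted")
        wmask = windows["chrom"].to_numpy() == c
        ws = windows.loc[wmask, "start"].to_numpy()
        we = windows.loc[wmask, "end"].to_numpy()
        offset = sel[0] if len(sel) else 0
        # pos is 1-based: window [s, e) covers pos in [s+1, e]
        lo[wmask] = offset + np.searchsorted(cpos, ws + 1, side="left")
        hi[wmask] = offset + np.searchsorted(cpos, we, side="right")
    return lo, hi


def z_transform(
    windows: pd.DataFrame,
    value_col: str = "value",
    partition_col: str | None = "partition",
    out_col: str = "zscore",
) -> pd.DataFrame:
    """Z-score window values within each chromosome partition.

    Autosomes + X-PAR and X-nonPAR are transformed separately (they have
    different drift expectations), so ``partition_col`` names the grouping
    column; ``None`` treats all windows as one partition. Uses the sample
    standard deviation (N-1). Windows with missing values get NaN z-scores
    and are excluded from the mean/sd.
    """
    out = windows.copy()
    values = out[value_col].to_numpy(dtype=float)
    z = np.full(len(out), np.nan)
    if partition_col is None:
        groups = [np.ones(len(out), dtype=bool)]
    else:
        groups = [
            (out[partition_col] == p).to_numpy()
            for p in pd.unique(out[partition_col])
        ]
    for g in groups:
        vals = values[g]
        finite = np.isfinite(vals)
        if finite.sum() < 2:
            raise ValueError("need >= 2 finite window values per partition")
        mu = vals[finite].mean()
        sd = vals[finite].std(ddof=1)
        if sd == 0:
            raise ValueError("zero standard deviation in partition; Z undefined")
        zg = np.full(len(vals), np.nan)
        zg[finite] = (vals[finite] - mu) / sd
        z[g] = zg
    out[out_col] = z
    return out


def percentile_threshold(values, q: float) -> float:
    """Linear-interpolation ("type 7") percentile of ``values``.

    This is the definition used for every calibrated threshold in the
    package, so thresholds are reproducible from stored window values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot take a percentile of no values")
    if not 0 <= q <= 100:
        raise ValueError("percentile q must be in [0, 100]")
    return float(np.percentile(values, q, method="linear"))


def merge_regions(
    windows: pd.DataFrame,
    max_gap: int = 0,
    value_col: str = "value",
    source: str | None = None,
) -> pd.DataFrame:
    """Merge passing windows whose inter-window gap is <= ``max_gap``.

    Overlapping or book-ended windows always merge (gap <= 0). Returns
    candidate regions with the peak member value and member window count.
    The output covers exactly the union of the inputs - no coordinates are
    invented.
    """
    cols = ["chrom", "start", "end", "peak", "n_windows"]
    if source is not None:
        cols.append("source")
    if len(windows) == 0:
        return pd.DataFrame({c: [] for c in cols})
    df = windows.sort_values(["chrom", "start", "end"], kind="mergesort")
    regions = []
    cur = None
    for row in df.itertuples(index=False):
        val = getattr(row, value_col) if value_col in df.columns else np.nan
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.start - cur["end"] <= max_gap
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["peak"] = np.nanmax([cur["peak"], val])
            cur["n_windows"] += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "peak": val,
                "n_windows": 1,
            }
    regions.append(cur)
    out = pd.DataFrame(regions)
    if source is not None:
        out["source"] = source
    return out


def write_bed(regions: pd.DataFrame, path, name_col: str | None = None) -> None:
    """Write regions as BED (0-based half-open)."""
    df = regions[["chrom", "start", "end"]].copy()
    if name_col is not None:
        df["name"] = regions[name_col]
    df.to_csv(path, sep="\t", header=False, index=False)
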
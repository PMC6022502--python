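"""Windowed read-depth copy number and the V_ST differentiation scan.

Copy number is estimated from windowed read depth (3-kb windows by default):
depth is GC-corrected against designated control (copy-number-2) windows,
normalised so the control mean maps to CN = 2, and quality-controlled per
sample with a signal-to-noise ratio (control-window mean depth / sd).

V_ST is the copy-number analogue of F_ST: for a window,

    V_ST = (V_T - V_S) / V_T

where V_T is the variance of copy number across all dog + wolf samples and
V_S the size-weighted mean of the within-population variances (population
variances, denominator N, so identical distributions give exactly 0).
Outlier calling requires a copy-number range of at least 1.5 across samples
and a Z-transformed V_ST greater than 5 (autosomes / X-PAR) or 3 (X-nonPAR);
male X-nonPAR copy numbers are doubled beforehand, and only outlier runs
spanning more than one window are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_windows import merge_regions, z_transform
from .variant_io import SamplePanel

__all__ = [
    "gc_correct_depth",
    "estimate_copy_number",
    "sample_snr",
    "double_male_nonpar",
    "vst",
    "call_vst_outliers",
]


def gc_correct_depth(
    depth: np.ndarray,
    gc: np.ndarray,
    control_mask: np.ndarray,
    bin_width: float = 0.01,
) -> np.ndarray:
    """Correct per-window depth for GC bias using control windows.

    Per sample, windows are binned by GC fraction (1% bins); the corrected
    depth is raw * (global control mean / control mean of the window's GC
    bin). Windows whose GC bin holds no control window are uncorrectable and
    set to NaN. With a single GC value everywhere the correction is exact
    identity.
    """
    depth = np.asarray(depth, dtype=float)
    gc = np.asarray(gc, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if depth.shape[0] != len(gc) or len(gc) != len(control_mask):
        raise ValueError("depth, gc and control mask must align")
    if not control_mask.any():
        raise ValueError("no control windows designated")
    bins = np.floor(gc / bin_width).astype(int)
    nbin = bins.max() + 1
    out = np.empty_like(depth)
    ctrl_bins = bins[control_mask]
    for j in range(depth.shape[1]):
        ctrl = depth[control_mask, j]
        global_mean = ctrl.mean()
        sums = np.bincount(ctrl_bins, weights=ctrl, minlength=nbin)
        counts = np.bincount(ctrl_bins, minlength=nbin)
        with np.errstate(invalid="ignore", divide="ignore"):
            bin_mean = sums / counts
        factor = global_mean / bin_mean[bins]  # NaN where bin empty
        out[:, j] = depth[:, j] * factor
    return out


def estimate_copy_number(corrected: np.ndarray, control_mask: np.ndarray) -> np.ndarray:
    """CN = 2 * corrected depth / per-sample mean corrected control depth."""
    corrected = np.asarray(corrected, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    ctrl_mean = np.nanmean(corrected[control_mask], axis=0)
    if np.any(~np.isfinite(ctrl_mean)) or np.any(ctrl_mean <= 0):
        raise ValueError("control windows give a non-positive mean depth")
    return 2.0 * corrected / ctrl_mean


def sample_snr(depth: np.ndarray, control_mask: np.ndarray) -> np.ndarray:
    """Per-sample SNR: mean control-window depth / its sample sd."""
    depth = np.asarray(depth, dtype=float)
    ctrl = depth[np.asarray(control_mask, dtype=bool)]
    if ctrl.shape[0] < 2:
        raise ValueError("need at least 2 control windows for SNR")
    sd = ctrl.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant control depth; SNR undefined")
    return ctrl.mean(axis=0) / sd


def double_male_nonpar(
    cn: np.ndarray, panel: SamplePanel, samples: list[str], nonpar_mask: np.ndarray
) -> np.ndarray:
    """Double male copy numbers on X-nonPAR windows (hemizygous males)."""
    out = np.asarray(cn, dtype=float).copy()
    male = np.array([panel.sex_of(s) == "male" for s in samples], dtype=bool)
    nonpar = np.asarray(nonpar_mask, dtype=bool)
    if nonpar.any() and male.any():
        out[np.ix_(nonpar, male)] *= 2.0
    return out


def vst(
    cn: np.ndarray,
    panel: SamplePanel,
    samples: list[str],
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Per-window V_ST records (V_T, V_S, vst, cn_range).

    ``cn`` is (n_windows, n_samples) with male X-nonPAR values already
    doubled. Windows with V_T = 0 emit no value (NaN). Both populations need
    at least 2 samples.
    """
    cn = np.asarray(cn, dtype=float)
    dog_idx = [samples.index(s) for s in panel.dogs]
    wolf_idx = [samples.index(s) for s in panel.wolves]
    if len(dog_idx) < 2 or len(wolf_idx) < 2:
        raise ValueError("V_ST needs >= 2 samples in each population")
    both = dog_idx + wolf_idx
    x = cn[:, both]
    v_t = x.var(axis=1)  # population variance, denominator N
    v_dog = cn[:, dog_idx].var(axis=1)
    v_wolf = cn[:, wolf_idx].var(axis=1)
    n_d, n_w = len(dog_idx), len(wolf_idx)
    v_s = (v_dog * n_d + v_wolf * n_w) / (n_d + n_w)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(v_t > 0, (v_t - v_s) / v_t, np.nan)
    out = windows.copy()
    out["v_t"] = v_t
    out["v_s"] = v_s
    out["value"] = v
    out["cn_range"] = x.max(axis=1) - x.min(axis=1)
    return out


def call_vst_outliers(
    records: pd.DataFrame,
    z_auto: float = 5.0,
    z_nonpar: float = 3.0,
    min_cn_range: float = 1.5,
    partition_col: str | None = None,
) -> pd.DataFrame:
    """Copy-number outlier regions from V_ST records.

    Keeps windows with cn_range >= 1.5 and Z-transformed V_ST strictly
    greater than 5 (autosome/X-PAR) or 3 (X-nonPAR); adjacent passing
    windows merge, and regions spanning a single window are discarded. The
    Z-transform excludes no-value (V_T = 0) windows.
    """
    df = records[np.isfinite(records["value"])].copy()
    if len(df) == 0:
        return merge_regions(df.head(0), value_col="value", source="vst")
    df = z_transform(df, partition_col=partition_col)
    zcut = (
        np.where(df[partition_col] == "x_nonpar", z_nonpar, z_auto)
        if partition_col
        else z_auto
    )
    passing = df[(df["cn_range"] >= min_cn_range) & (df["zscore"] > zcut)]
    regions = merge_regions(passing, max_gap=0, value_col="value", source="vst")
    return regions[regions["n_windows"] > 1].reset_index(drop=True)
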
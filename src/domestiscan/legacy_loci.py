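"""Re-evaluation of previously published candidate loci under this cohort.

Candidate domestication regions published from other cohorts (breed-dog
F_ST scans and the like) can be re-assessed against the present cohort: per
locus the maximum windowed F_ST across overlapping scan windows is looked
up, together with the H_P and ΔH_P of that same maximal window, and the
locus passes only if all three meet the cohort's thresholds. Statistics are
always computed from the current cohort, never taken from the source study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["refilter_loci"]


def refilter_loci(
    loci: pd.DataFrame,
    scan_windows: pd.DataFrame,
    fst_threshold: float,
    hp_threshold: float,
    dhp_threshold: float,
) -> pd.DataFrame:
    """Apply the F_ST / H_P / ΔH_P cascade to externally defined loci.

    ``loci``: columns source, chrom, start, end (0-based half-open).
    ``scan_windows``: F_ST scan windows carrying ``value`` (windowed F_ST),
    ``hp`` and ``delta_hp`` columns for the same cohort. A locus overlaps a
    window by >= 1 bp to count; H_P/ΔH_P are read from the maximal-F_ST
    window. Loci overlapping no usable window are flagged ``no_data``.
    """
    usable = scan_windows[
        scan_windows["usable"] if "usable" in scan_windows else slice(None)
    ]
    wchrom = usable["chrom"].to_numpy(dtype=object)
    wstart = usable["start"].to_numpy()
    wend = usable["end"].to_numpy()
    wval = usable["value"].to_numpy(dtype=float)
    whp = usable["hp"].to_numpy(dtype=float)
    wdhp = usable["delta_hp"].to_numpy(dtype=float)

    rows = []
    for row in loci.itertuples(index=False):
        if row.end <= row.start:
            raise ValueError(f"zero-width locus {row.chrom}:{row.start}-{row.end}")
        hit = (wchrom == row.chrom) & (wstart < row.end) & (wend > row.start)
        hit &= np.isfinite(wval)
        rec = {
            "source": getattr(row, "source", ""),
            "chrom": row.chrom,
            "start": row.start,
            "end": row.end,
        }
        if not hit.any():
            rec.update(
                max_fst=np.nan, hp=np.nan, delta_hp=np.nan,
                pass_fst=False, pass_hp=False, pass_dhp=False,
                passes=False, no_data=True,
            )
        else:
            best = np.flatnonzero(hit)[np.argmax(wval[hit])]
            rec.update(
                max_fst=wval[best],
                hp=whp[best],
                delta_hp=wdhp[best],
                no_data=False,
            )
            rec["pass_fst"] = rec["max_fst"] > fst_threshold
            rec["pass_hp"] = np.isfinite(rec["hp"]) and rec["hp"] < hp_threshold
            rec["pass_dhp"] = (
                np.isfinite(rec["delta_hp"]) and rec["delta_hp"] <= dhp_threshold
            )
            rec["passes"] = rec["pass_fst"] and rec["pass_hp"] and rec["pass_dhp"]
        rows.append(rec)
    return pd.DataFrame(rows)
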
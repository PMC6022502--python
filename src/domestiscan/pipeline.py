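"""End-to-end orchestration: filter -> scan -> filter -> merge -> enrich.

:func:`run_pipeline` wires the stages together from a
:class:`PipelineConfig`, writes window TSVs and candidate-region BEDs to the
output directory, and records a JSON manifest with the seeds, thresholds and
per-stage window counts (the counts are monotone non-increasing through the
filter cascade, which the tests assert). Calibrated thresholds are inputs
here - produce them with :mod:`domestiscan.neutral_null` - so a pipeline run
is deterministic given its config.

:func:`genotype_matrix` renders the classic candidate-region genotype
visualisation: samples (dogs, then wolves, then ancients) by SNPs, each cell
0/1/2 for hom-ref / het / hom-alt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome_windows import make_windows, merge_regions, write_bed
from .heterozygosity import apply_hp_filters, window_hp
from .fst_scan import fst_sites, windowed_fst
from .variant_io import SamplePanel, load_variants, maf_filter, allele_frequencies
from .xpclr_scan import (
    GeneticMap,
    XpclrConfig,
    average_grid_windows,
    xpclr_score_grid,
)

__all__ = ["PipelineConfig", "run_pipeline", "genotype_matrix"]


@dataclass
class PipelineConfig:
    """Paths, scan parameters and thresholds for one pipeline run."""

    vcf: str
    panel: str
    outdir: str
    par_bed: str | None = None
    # site filters
    min_minor_count: int = 3
    # F_ST scan
    fst_window: int = 200_000
    fst_step: int = 50_000
    fst_min_snps: int = 10
    fst_threshold: float | None = None  # calibrated; None -> skip F_ST cascade
    # XP-CLR scan
    xpclr_grid: int = 2_000
    xpclr_snp_window: int = 50_000
    xpclr_window: int = 25_000
    xpclr_step: int = 10_000
    xpclr_min_grids: int = 5
    xpclr_threshold: float | None = None
    xpclr_merge_gap: int = 50_000
    # heterozygosity filters
    hp_threshold: float | None = None  # from the simulated H_P 0.1th percentile
    dhp_percentile: float = 95.0  # genome-wide ΔHp percentile; above -> removed
    dhp_cap: float = 0.0  # operative ΔHp threshold never exceeds this
    # enrichment (optional)
    genes_bed: str | None = None
    annotations_tsv: str | None = None
    ontology_tsv: str | None = None
    n_permutations: int = 1000
    enrich_flank: int = 50_000
    seed: int = 0

    def validate_paths(self) -> None:
        for name in ("vcf", "panel", "par_bed", "genes_bed", "annotations_tsv",
                     "ontology_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: {p} does not exist")


def _hp_columns(af, windows, ancient_gt):
    hp = window_hp(af, windows, ancient_gt=ancient_gt)
    cols = ["hp"] + (["hp_with_ancient", "delta_hp"] if ancient_gt is not None else [])
    out = windows.copy()
    for c in cols:
        out[c] = hp[c].to_numpy()
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured scans; returns the manifest dict."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    panel = SamplePanel.from_tsv(config.panel)
    par = None
    if config.par_bed:
        from .variant_io import read_par_bed

        par = read_par_bed(config.par_bed)
    table = load_variants(config.vcf, panel, par_intervals=par)
    manifest["stages"]["loaded_sites"] = table.n_sites
    table = maf_filter(table, panel, min_minor_count=config.min_minor_count)
    manifest["stages"]["post_maf_sites"] = table.n_sites
    chrom_lengths = table.chrom_lengths or {
        c: int(table.pos[table.chrom == c].max()) for c in np.unique(table.chrom)
    }

    af = allele_frequencies(table, panel)
    anc = panel.ancients
    ancient_gt = table.gt[:, table.sample_index(anc)] if anc else None

    thresholds: dict = {
        "fst": config.fst_threshold,
        "xpclr": config.xpclr_threshold,
        "hp": config.hp_threshold,
    }

    # ---- F_ST cascade ----------------------------------------------------
    if config.fst_threshold is not None:
        windows = make_windows(chrom_lengths, config.fst_window, config.fst_step)
        fw = windowed_fst(fst_sites(af), windows, min_snps=config.fst_min_snps)
        fw = _hp_columns(af, fw, ancient_gt)
        bg = ~(fw["usable"] & (fw["value"] > config.fst_threshold))
        dhp_thr = min(
            float(np.nanpercentile(fw.loc[bg, "delta_hp"], config.dhp_percentile)),
            config.dhp_cap,
        )
        fw = apply_hp_filters(fw, config.hp_threshold, dhp_thr)
        usable = fw[fw["usable"]]
        sig = usable[usable["value"] > config.fst_threshold]
        final = sig[sig["pass_hp_filters"]]
        regions = merge_regions(final, max_gap=0, value_col="value", source="fst")
        fw.to_csv(outdir / "fst_windows.tsv", sep="\t", index=False)
        write_bed(regions, outdir / "fst_candidates.bed")
        manifest["stages"]["fst"] = {
            "windows_usable": int(len(usable)),
            "windows_significant": int(len(sig)),
            "windows_after_hp_filters": int(len(final)),
            "candidate_regions": int(len(regions)),
        }
        thresholds["fst_dhp"] = dhp_thr

    # ---- XP-CLR cascade --------------------------------------------------
    if config.xpclr_threshold is not None:
        xc = XpclrConfig(
            grid_spacing=config.xpclr_grid, snp_window=config.xpclr_snp_window
        )
        grid = xpclr_score_grid(af, GeneticMap(), xc, chrom_lengths=chrom_lengths)
        xw = average_grid_windows(
            grid,
            chrom_lengths,
            win=config.xpclr_window,
            step=config.xpclr_step,
            min_grids=config.xpclr_min_grids,
        )
        xw = _hp_columns(af, xw, ancient_gt)
        bg = ~(xw["usable"] & (xw["value"] > config.xpclr_threshold))
        dhp_thr = min(
            float(np.nanpercentile(xw.loc[bg, "delta_hp"], config.dhp_percentile)),
            config.dhp_cap,
        )
        xw = apply_hp_filters(xw, config.hp_threshold, dhp_thr)
        usable = xw[xw["usable"]]
        sig = usable[usable["value"] > config.xpclr_threshold]
        final = sig[sig["pass_hp_filters"]]
        regions = merge_regions(
            final, max_gap=config.xpclr_merge_gap, value_col="value", source="xpclr"
        )
        xw.to_csv(outdir / "xpclr_windows.tsv", sep="\t", index=False)
        write_bed(regions, outdir / "xpclr_candidates.bed")
        manifest["stages"]["xpclr"] = {
            "windows_usable": int(len(usable)),
            "windows_significant": int(len(sig)),
            "windows_after_hp_filters": int(len(final)),
            "candidate_regions": int(len(regions)),
        }
        thresholds["xpclr_dhp"] = dhp_thr

        # ---- enrichment on the XP-CLR candidates -------------------------
        if config.genes_bed and config.annotations_tsv and config.ontology_tsv:
            from .enrichment import (
                Ontology,
                filter_enriched_terms,
                permutation_pvalues,
            )

            genes = pd.read_csv(
                config.genes_bed, sep="\t", header=None,
                names=["chrom", "start", "end", "gene", "score", "strand"],
            )
            ontology = Ontology.from_tables(
                pd.read_csv(config.annotations_tsv, sep="\t"),
                pd.read_csv(config.ontology_tsv, sep="\t"),
            )
            if len(regions):
                results = permutation_pvalues(
                    regions, genes, ontology, chrom_lengths,
                    n_permutations=config.n_permutations,
                    seed=config.seed, flank=config.enrich_flank,
                )
                enriched = filter_enriched_terms(results)
                results.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                enriched.to_csv(outdir / "enriched_terms.tsv", sep="\t", index=False)
                manifest["stages"]["enrichment"] = {
                    "terms_tested": int(len(results)),
                    "terms_enriched": int(len(enriched)),
                }

    manifest["thresholds"] = thresholds
    manifest["parameters"] = {
        k: v for k, v in asdict(config).items() if not isinstance(v, (dict,))
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def genotype_matrix(table, panel: SamplePanel, region: tuple) -> pd.DataFrame:
    """Samples-by-SNPs genotype matrix for a region.

    Rows are samples grouped dogs / wolves / ancients; columns are the SNPs
    in ``region`` (chrom, start, end; 0-based half-open) in position order;
    cells are 0 (hom-ref), 1 (het), 2 (hom-alt).
    """
    chrom, start, end = region
    idx = np.flatnonzero(
        (table.chrom == chrom) & (table.pos - 1 >= start) & (table.pos - 1 < end)
    )
    if len(idx) == 0:
        import warnings

        warnings.warn(f"no SNPs in region {chrom}:{start}-{end}; empty matrix")
    order = panel.dogs + panel.wolves + panel.ancients
    order = [s for s in order if s in table.samples]
    sidx = table.sample_index(order)
    mat = table.gt[np.ix_(idx, sidx)].T
    cols = [f"{chrom}:{p}" for p in table.pos[idx]]
    return pd.DataFrame(mat, index=order, columns=cols)


def save_genotype_matrix(matrix: pd.DataFrame, tsv_path, png_path=None) -> None:
    """Write the genotype matrix as TSV (canonical) and optionally as an
    image (samples x SNPs, three-colour)."""
    matrix.to_csv(tsv_path, sep="\t")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, matrix.shape[1] / 20), max(3, matrix.shape[0] / 8))
        )
        ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis",
                  interpolation="nearest", vmin=0, vmax=2)
        ax.set_xlabel("SNPs")
        ax.set_yticks(range(matrix.shape[0]))
        ax.set_yticklabels(matrix.index, fontsize=5)
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
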
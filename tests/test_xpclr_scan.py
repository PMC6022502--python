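import numpy as np
import pandas as pd
import pytest

from domestiscan.variant_io import AlleleFrequencyTable
from domestiscan.xpclr_scan import (
    GeneticMap,
    XpclrConfig,
    average_grid_windows,
    estimate_omega,
    genetic_distances,
    xpclr_candidates,
    xpclr_score_grid,
)


def _af(pos, p_dog, p_wolf, n_dog=43, n_wolf=10, chrom="1"):
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    p_dog = np.asarray(p_dog, dtype=float)
    p_wolf = np.asarray(p_wolf, dtype=float)
    return AlleleFrequencyTable(
        chrom=np.full(n, chrom, dtype=object),
        pos=pos,
        p_dog=p_dog,
        p_wolf=p_wolf,
        n_dog=np.full(n, float(n_dog)),
        n_wolf=np.full(n, float(n_wolf)),
        n_maj=np.maximum(p_dog, 1 - p_dog) * 2 * n_dog,
        n_min=np.minimum(p_dog, 1 - p_dog) * 2 * n_dog,
        major_is_alt=p_dog > 0.5,
        region_class=np.zeros(n, dtype=np.int8),
    )


class TestGeneticDistances:
    def test_linear_midpoint_between_anchors(self):
        gmap = GeneticMap(
            table=pd.DataFrame(
                {"chrom": ["1", "1"], "pos": [0, 1_000_000], "morgans": [0.0, 0.01]}
            )
        )
        assert genetic_distances([500_000], gmap)[0] == pytest.approx(0.005)

    def test_anchor_positions_exact(self):
        gmap = GeneticMap(
            table=pd.DataFrame(
                {"chrom": ["1"] * 3, "pos": [0, 10_000, 50_000],
                 "morgans": [0.0, 0.0002, 0.0004]}
            )
        )
        assert genetic_distances([10_000], gmap)[0] == pytest.approx(0.0002)

    def test_uniform_fallback_rate(self):
        gmap = GeneticMap(rate=1e-8)  # 1 cM/Mb
        assert genetic_distances([2_500_000], gmap)[0] == pytest.approx(0.025)

    def test_terminal_extrapolation(self):
        gmap = GeneticMap(
            table=pd.DataFrame(
                {"chrom": ["1", "1"], "pos": [1000, 2000], "morgans": [0.001, 0.003]}
            )
        )
        # beyond the last anchor: terminal segment rate 2e-6 / bp
        assert genetic_distances([3000], gmap)[0] == pytest.approx(0.005)

    def test_unsorted_map_errors(self):
        gmap = GeneticMap(
            table=pd.DataFrame(
                {"chrom": ["1", "1"], "pos": [2000, 1000], "morgans": [0.0, 0.01]}
            )
        )
        with pytest.raises(ValueError):
            gmap.distances("1", [1500])


class TestXpclrScoreGrid:
    def test_identical_frequencies_score_near_zero(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 200_000), 150, replace=False))
        p = rng.uniform(0.1, 0.9, size=150)
        af = _af(pos, p, p)
        grid = xpclr_score_grid(af, config=XpclrConfig(omega=0.2),
                                chrom_lengths={"1": 200_000})
        ok = grid[grid["ok"]]
        assert (ok["score"] >= 0).all()
        assert ok["score"].max() < 1.0  # null model is the optimum

    def test_selection_grid_of_zero_only_gives_zero(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 100_000), 60, replace=False))
        af = _af(pos, rng.uniform(0, 1, 60), rng.uniform(0.1, 0.9, 60))
        grid = xpclr_score_grid(
            af, config=XpclrConfig(omega=0.2, sel_grid=(0.0,)),
            chrom_lengths={"1": 100_000},
        )
        assert np.allclose(grid.loc[grid["ok"], "score"], 0.0)

    def test_scores_non_negative_and_flags(self):
        af = _af([50_000], [0.9], [0.2])
        grid = xpclr_score_grid(af, config=XpclrConfig(omega=0.2),
                                chrom_lengths={"1": 200_000})
        assert (grid.loc[grid["ok"], "score"] >= 0).all()
        far = grid[~grid["ok"]]
        assert (far["n_snps"] == 0).all() and far["score"].isna().all()

    def test_monotone_in_differentiation(self):
        """Pushing dog frequencies further from the wolf frequencies (toward
        hitchhiking fixation) never decreases the grid score."""
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 50_000), 40, replace=False))
        p2 = rng.uniform(0.3, 0.7, size=40)
        prev = -np.inf
        for push in np.linspace(0.0, 1.0, 6):
            p1 = p2 + (1.0 - p2) * push  # move toward fixation of ALT
            af = _af(pos, p1, p2)
            grid = xpclr_score_grid(af, config=XpclrConfig(omega=0.2),
                                    chrom_lengths={"1": 50_000})
            score = grid.loc[grid["gpos"] == 24_000, "score"].iloc[0]
            assert score >= prev - 1e-9
            prev = score

    def test_planted_sweep_beats_neutral_background(self):
        from domestiscan import SweepSpec, generate_cohort, two_population_model
        from domestiscan.workflows import prepare_frequencies

        model = two_population_model()
        sweep = SweepSpec("1", 800_000, 1_200_000, residual=0.02)
        cohort = generate_cohort(model, {"1": 2_000_000}, sweeps=[sweep],
                                 n_dogs=43, n_wolves=10, seed=13)
        neutral = generate_cohort(model, {"1": 5_000_000},
                                  n_dogs=43, n_wolves=10, seed=14)
        af_s, _ = prepare_frequencies(cohort.variants, cohort.panel)
        af_n, _ = prepare_frequencies(neutral.variants, neutral.panel)
        gs = xpclr_score_grid(af_s, chrom_lengths={"1": 2_000_000})
        gn = xpclr_score_grid(af_n, chrom_lengths={"1": 5_000_000})
        thr = np.nanpercentile(gn.loc[gn["ok"], "score"], 99)
        inside = gs[(gs["gpos"] >= 900_000) & (gs["gpos"] <= 1_100_000)]
        assert (inside["score"] > thr).mean() > 0.8


class TestAverageGridWindows:
    def _grid(self, gpos, scores):
        return pd.DataFrame(
            {"chrom": "1", "gpos": gpos, "score": scores,
             "n_snps": 10, "ok": True}
        )

    def test_fewer_than_five_grids_removed(self):
        grid = self._grid([0, 2000, 4000, 6000], [1.0] * 4)
        out = average_grid_windows(grid, {"1": 25_000}, win=25_000, step=25_000)
        assert not out["usable"].iloc[0]

    def test_five_equal_scores_give_that_value(self):
        grid = self._grid([0, 2000, 4000, 6000, 8000], [7.0] * 5)
        out = average_grid_windows(grid, {"1": 25_000}, win=25_000, step=25_000)
        assert out["value"].iloc[0] == pytest.approx(7.0)

    def test_mean_of_scores(self):
        grid = self._grid([0, 2000, 4000, 6000, 8000], [10, 20, 30, 40, 50])
        out = average_grid_windows(grid, {"1": 25_000}, win=25_000, step=25_000)
        assert out["value"].iloc[0] == pytest.approx(30.0)

    def test_permutation_invariance_within_window(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 50, size=5)
        a = average_grid_windows(self._grid([0, 2000, 4000, 6000, 8000], scores),
                                 {"1": 25_000}, win=25_000, step=25_000)
        b = average_grid_windows(
            self._grid([0, 2000, 4000, 6000, 8000], scores[::-1]),
            {"1": 25_000}, win=25_000, step=25_000,
        )
        assert a["value"].iloc[0] == pytest.approx(b["value"].iloc[0])


class TestXpclrCandidates:
    def _windows(self, starts, values, hp=None, dhp=None):
        df = pd.DataFrame(
            {"chrom": "1", "start": starts, "end": np.asarray(starts) + 25_000,
             "value": values, "usable": True}
        )
        if hp is not None:
            df["hp"] = hp
            df["delta_hp"] = dhp
        return df

    def test_merge_within_50kb(self):
        w = self._windows([0, 70_000], [30.0, 30.0])
        assert len(xpclr_candidates(w, threshold=20.0)) == 1
        w = self._windows([0, 80_000], [30.0, 30.0])
        assert len(xpclr_candidates(w, threshold=20.0)) == 2

    def test_hp_and_dhp_filters_exclude(self):
        w = self._windows(
            [0, 100_000, 200_000],
            [30.0, 30.0, 30.0],
            hp=[0.01, 0.30, 0.01],
            dhp=[-0.001, -0.001, 0.02],
        )
        out = xpclr_candidates(w, threshold=20.0, hp_threshold=0.06,
                               dhp_threshold=0.004)
        # high hp excluded; ancient non-carrier (high ΔHp) excluded
        assert len(out) == 1 and out.iloc[0]["start"] == 0

    def test_missing_thresholds_error(self):
        w = self._windows([0], [30.0], hp=[0.01], dhp=[0.0])
        with pytest.raises(ValueError):
            xpclr_candidates(w, threshold=None)
        with pytest.raises(ValueError):
            xpclr_candidates(w, threshold=20.0)


def test_estimate_omega_scales_with_divergence():
    rng = np.random.default_rng(8)
    pos = np.sort(rng.choice(np.arange(1, 10**6), 2000, replace=False))
    p2 = rng.uniform(0.1, 0.9, size=2000)
    for w_true in (0.05, 0.3):
        p1 = np.clip(p2 + rng.normal(0, np.sqrt(w_true * p2 * (1 - p2))), 0, 1)
        af = _af(pos, p1, p2)
        est = estimate_omega(af)
        assert est == pytest.approx(w_true, rel=0.3)
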
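import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from domestiscan import (
    CnvSpec,
    SweepSpec,
    allele_frequencies,
    generate_ancient_samples,
    generate_cohort,
    generate_depth_profiles,
    generate_toy_annotation,
    make_windows,
    window_hp,
)
from domestiscan.enrichment import Ontology
from domestiscan.fst_scan import fst_sites
from domestiscan.synthetic_data import default_gc_bias
from domestiscan.variant_io import SamplePanel


class TestGenerateCohort:
    def test_seeded_rerun_is_identical(self, fast_model):
        kw = dict(
            chrom_lengths={"1": 400_000},
            sweeps=[SweepSpec("1", 100_000, 200_000, residual=0.1)],
            n_dogs=6,
            n_wolves=4,
            seed=1,
        )
        a = generate_cohort(fast_model, **kw)
        b = generate_cohort(fast_model, **kw)
        assert a.variants.equals(b.variants)
        assert np.array_equal(a.ancient_haplotypes, b.ancient_haplotypes)

    def test_single_population_fst_near_zero(self, single_pop_model):
        cohort = generate_cohort(
            single_pop_model, {"1": 2_000_000}, n_dogs=12, n_wolves=10, seed=3
        )
        af = allele_frequencies(cohort.variants, cohort.panel)
        sites = fst_sites(af)
        mean_fst = sites["num"].mean() / sites["den"].mean()
        assert abs(mean_fst) < 0.02

    def test_residual_zero_sweep_gives_hp_zero(self, fast_model):
        sweep = SweepSpec("1", 500_000, 1_000_000, residual=0.0)
        cohort = generate_cohort(
            fast_model, {"1": 1_500_000}, sweeps=[sweep], n_dogs=10, n_wolves=6, seed=5
        )
        af = allele_frequencies(cohort.variants, cohort.panel)
        windows = make_windows({"1": 1_500_000}, 100_000, 100_000)
        hp = window_hp(af, windows)
        contained = (windows["start"] >= 500_000) & (windows["end"] <= 1_000_000)
        inside = hp.loc[contained & (hp["n_sites"] > 0), "hp"]
        assert len(inside) > 0 and (inside == 0.0).all()

    def test_sweep_validation_errors(self, fast_model):
        with pytest.raises(ValueError, match="overlapping"):
            generate_cohort(
                fast_model,
                {"1": 1_000_000},
                sweeps=[SweepSpec("1", 0, 500_000), SweepSpec("1", 400_000, 700_000)],
                n_dogs=4, n_wolves=4, seed=0,
            )
        with pytest.raises(ValueError, match="outside"):
            generate_cohort(
                fast_model, {"1": 1_000_000},
                sweeps=[SweepSpec("1", 900_000, 1_100_000)],
                n_dogs=4, n_wolves=4, seed=0,
            )
        with pytest.raises(ValueError, match="chrom_lengths"):
            generate_cohort(
                fast_model, {"1": 1_000_000}, sweeps=[SweepSpec("2", 0, 100)],
                n_dogs=4, n_wolves=4, seed=0,
            )

    def test_panel_matches_sample_counts(self, small_cohort):
        panel = small_cohort.panel
        assert len(panel.dogs) == 12 and len(panel.wolves) == 8
        assert len(panel.ancients) == 2
        assert small_cohort.variants.gt.shape[1] == 20


class TestGenerateAncientSamples:
    def test_carrier_ancients_match_swept_haplotype(self, small_cohort):
        anc = generate_ancient_samples(
            small_cohort, 2, carrier_policy={0: True}, seed=1
        )
        idx, maj = small_cohort.swept_haplotype(0)
        expected = (2 * maj).astype(np.int8)
        assert np.array_equal(anc[idx], np.column_stack([expected, expected]))

    def test_carrier_delta_hp_non_positive(self, small_cohort):
        anc = generate_ancient_samples(small_cohort, 2, carrier_policy={0: True}, seed=1)
        af = allele_frequencies(small_cohort.variants, small_cohort.panel)
        windows = make_windows({"1": 1_500_000}, 100_000, 100_000)
        hp = window_hp(af, windows, ancient_gt=anc)
        contained = (windows["start"] >= 500_000) & (windows["end"] <= 900_000)
        assert (hp.loc[contained, "delta_hp"].dropna() <= 1e-12).all()

    def test_noncarrier_delta_hp_positive(self, small_cohort):
        anc = generate_ancient_samples(small_cohort, 2, carrier_policy={0: False}, seed=1)
        af = allele_frequencies(small_cohort.variants, small_cohort.panel)
        windows = pd.DataFrame(
            {"chrom": ["1"], "start": [500_000], "end": [900_000]}
        )
        hp = window_hp(af, windows, ancient_gt=anc)
        assert hp["delta_hp"].iloc[0] > 0

    def test_neutral_ancients_look_like_modern_dogs(self, fast_model):
        """Without sweeps, ancient allele frequencies are statistically
        indistinguishable from modern dogs (two-proportion z-test
        non-significant at alpha=0.01 for >= 99% of sites)."""
        cohort = generate_cohort(
            fast_model, {"1": 3_000_000}, n_dogs=20, n_wolves=4, seed=9, n_ancient=10
        )
        anc = generate_ancient_samples(cohort, 10, seed=2)
        dogs = cohort.variants.sample_index(cohort.panel.dogs)
        dog_gt = cohort.variants.gt[:, dogs]
        n1, n2 = 2 * dog_gt.shape[1], 2 * anc.shape[1]
        p1 = dog_gt.sum(axis=1) / n1
        p2 = anc.sum(axis=1) / n2
        pool = (dog_gt.sum(axis=1) + anc.sum(axis=1)) / (n1 + n2)
        keep = (pool > 0) & (pool < 1)
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))[keep]
        z = (p1[keep] - p2[keep]) / se
        pvals = 2 * norm.sf(np.abs(z))
        # ~99% expected non-significant at alpha=0.01; LD between sites
        # overdisperses the count, so allow the binomial-scale slack
        assert (pvals >= 0.01).mean() >= 0.98

    def test_too_many_ancients_errors(self, small_cohort):
        with pytest.raises(ValueError, match="not enough"):
            generate_ancient_samples(small_cohort, 5, seed=0)


class TestGenerateDepthProfiles:
    def _panel(self):
        return SamplePanel(
            pd.DataFrame(
                {
                    "sample": ["d1", "d2", "w1", "w2"],
                    "population": ["dog", "dog", "wolf", "wolf"],
                    "sex": ["male", "female", "male", "female"],
                }
            )
        )

    def test_noise_free_flat_bias_exact(self):
        tracks = generate_depth_profiles(
            self._panel(), {"1": 30_000}, [], mean_depth=25.0,
            gc_bias_curve=lambda g: np.ones_like(np.asarray(g, float)),
            noise_sd=0.0, seed=0,
        )
        assert np.allclose(tracks.depth, 25.0)

    def test_planted_cn4_doubles_depth(self):
        cnv = CnvSpec("1", 9_000, 15_000, {"dog": {4: 1.0}})
        tracks = generate_depth_profiles(
            self._panel(), {"1": 30_000}, [cnv], mean_depth=10.0,
            gc_bias_curve=lambda g: np.ones_like(np.asarray(g, float)),
            noise_sd=0.0, seed=0,
        )
        w = tracks.windows
        inside = ((w["start"] >= 9_000) & (w["end"] <= 15_000)).to_numpy()
        assert np.allclose(tracks.depth[inside][:, :2], 20.0)  # dogs
        assert np.allclose(tracks.depth[inside][:, 2:], 10.0)  # wolves

    def test_snr_matches_noise_level(self):
        from domestiscan.cnv_scan import sample_snr

        tracks = generate_depth_profiles(
            self._panel(), {"1": 45_000_000}, [], mean_depth=30.0,
            gc_bias_curve=lambda g: np.ones_like(np.asarray(g, float)),
            noise_sd=0.1, seed=4,
        )
        snr = sample_snr(tracks.depth, np.ones(len(tracks.windows), dtype=bool))
        assert np.allclose(snr, 10.0, rtol=0.1)

    def test_determinism_and_validation(self):
        kw = dict(chrom_lengths={"1": 60_000}, cnvs=[], seed=11)
        a = generate_depth_profiles(self._panel(), **kw)
        b = generate_depth_profiles(self._panel(), **kw)
        assert np.array_equal(a.depth, b.depth)
        with pytest.raises(ValueError, match="window size"):
            generate_depth_profiles(self._panel(), {"1": 1000}, [], window_size=0)

    def test_default_gc_bias_shape(self):
        gc = np.linspace(0.2, 0.7, 101)
        f = default_gc_bias(gc)
        assert f.max() <= 1.1 + 1e-9 and f.min() >= 0.6 - 1e-9
        assert f[np.argmin(np.abs(gc - 0.45))] == pytest.approx(1.1, abs=1e-3)


class TestGenerateToyAnnotation:
    def test_single_term_is_root_annotating_all(self):
        genes, annot, onto = generate_toy_annotation({"1": 5_000_000}, 10, 2, 1, seed=0)
        assert onto.empty
        assert set(annot["term"]) == {"term0000"}
        assert set(annot["gene"]) == set(genes["gene"])

    def test_propagation_to_ancestors(self):
        genes, annot, onto = generate_toy_annotation(
            {"1": 20_000_000}, 30, 3, 15, seed=1
        )
        ontology = Ontology.from_tables(annot, onto)
        root = "term0000"
        # DAG closure: a gene annotated to any term counts for the root
        assert ontology.term_genes[root] == frozenset(annot["gene"])
        for child, parent in onto.itertuples(index=False):
            assert ontology.term_genes[child] <= ontology.term_genes[parent]

    def test_genes_do_not_overlap(self):
        genes, _, _ = generate_toy_annotation({"1": 3_000_000, "2": 2_000_000},
                                              60, 3, 10, seed=2)
        for _, sub in genes.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_seeded_rerun_identical(self):
        a = generate_toy_annotation({"1": 2_000_000}, 20, 3, 8, seed=3)
        b = generate_toy_annotation({"1": 2_000_000}, 20, 3, 8, seed=3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_genes_cannot_fit_errors(self):
        with pytest.raises(ValueError, match="cannot fit"):
            generate_toy_annotation({"1": 50_000}, 100, 2, 5, seed=0)
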
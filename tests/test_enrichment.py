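import math

import numpy as np
import pandas as pd
import pytest

from domestiscan.enrichment import (
    Ontology,
    filter_enriched_terms,
    genes_near_regions,
    parent_child_test,
    permutation_pvalues,
    shuffle_regions,
)
from domestiscan.synthetic_data import generate_toy_annotation


def _ontology(parent_edges, gene_terms):
    annot = pd.DataFrame(
        [{"gene": g, "term": t} for g, ts in gene_terms.items() for t in ts]
    )
    parents = pd.DataFrame(parent_edges, columns=["child", "parent"])
    return Ontology.from_tables(annot, parents)


def _hypergeom_tail(k, M, n, N):
    """Exhaustive hypergeometric upper tail via exact combinatorics."""
    total = 0
    for j in range(k, min(n, N) + 1):
        total += math.comb(n, j) * math.comb(M - n, N - j)
    return total / math.comb(M, N)


class TestGenesNearRegions:
    GENES = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2"],
            "start": [110_000, 200_000, 500_000, 10_000],
            "end": [120_000, 210_000, 510_000, 20_000],
            "gene": ["near", "overlap2", "far", "other_chrom"],
            "score": 0,
            "strand": "+",
        }
    )

    def test_flank_inclusion_and_exclusion(self):
        regions = pd.DataFrame({"chrom": ["1"], "start": [130_000], "end": [160_000]})
        hits = genes_near_regions(regions, self.GENES, flank=50_000)
        # gene ending 10 kb upstream included; gene 340 kb away excluded
        assert set(hits["gene"]) == {"near", "overlap2"}
        # 40-kb gap -> included; the same gene 60 kb away -> excluded
        regions = pd.DataFrame({"chrom": ["1"], "start": [430_000], "end": [460_000]})
        hits = genes_near_regions(regions, self.GENES, flank=50_000)
        assert set(hits["gene"]) == {"far"}
        regions = pd.DataFrame({"chrom": ["1"], "start": [380_000], "end": [440_000]})
        hits = genes_near_regions(regions, self.GENES, flank=50_000)
        assert set(hits["gene"]) == set()

    def test_gene_spanning_two_regions_counts_loci(self):
        regions = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [195_000, 205_000], "end": [202_000, 215_000]}
        )
        hits = genes_near_regions(regions, self.GENES, flank=0)
        row = hits[hits["gene"] == "overlap2"].iloc[0]
        assert row["n_loci"] == 2


class TestParentChildTest:
    def test_root_term_p_is_one(self):
        onto = _ontology([("A", "root")], {"g1": ["A"], "g2": ["root"]})
        res = parent_child_test({"g1"}, onto, {"g1", "g2"}).set_index("term")
        assert res.loc["root", "p"] == 1.0

    def test_zero_hits_p_is_one(self):
        onto = _ontology([("A", "root")], {"g1": ["A"], "g2": ["root"]})
        res = parent_child_test({"g2"}, onto, {"g1", "g2"}).set_index("term")
        assert res.loc["A", "p"] == 1.0

    def test_toy_exact_probability(self):
        """A annotates 5 of the root's 100 genes; the test set is exactly
        those 5 -> p = 1 / C(100, 5)."""
        genes = [f"g{i}" for i in range(100)]
        gene_terms = {g: ["root"] for g in genes}
        for g in genes[:5]:
            gene_terms[g] = ["A"]
        onto = _ontology([("A", "root")], gene_terms)
        res = parent_child_test(set(genes[:5]), onto, set(genes)).set_index("term")
        assert res.loc["A", "p"] == pytest.approx(1 / math.comb(100, 5), rel=1e-9)

    def test_matches_exhaustive_enumeration_on_random_dags(self):
        """Parent-child (union) p equals the exhaustive hypergeometric tail
        on small random ontologies."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            genes = [f"g{i}" for i in range(int(rng.integers(8, 21)))]
            gene_terms = {}
            for g in genes:
                terms = ["root"]
                if rng.random() < 0.6:
                    terms.append("A")
                if rng.random() < 0.3:
                    terms.append("B")
                gene_terms[g] = terms
            onto = _ontology([("A", "root"), ("B", "A")], gene_terms)
            test = set(g for g in genes if rng.random() < 0.4)
            res = parent_child_test(test, onto, set(genes)).set_index("term")
            for term, parents in [("A", ["root"]), ("B", ["A"])]:
                pa = frozenset().union(*(onto.term_genes[p] for p in parents))
                m = len(onto.term_genes[term] & pa)
                k = len(onto.term_genes[term] & test)
                n_draw = len(test & pa)
                expected = _hypergeom_tail(k, len(pa), m, n_draw)
                assert res.loc[term, "p"] == pytest.approx(expected, abs=1e-12)

    def test_test_genes_must_be_in_universe(self):
        onto = _ontology([("A", "root")], {"g1": ["A"]})
        with pytest.raises(ValueError):
            parent_child_test({"gX"}, onto, {"g1"})

    def test_cyclic_ontology_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            _ontology([("A", "B"), ("B", "A")], {"g1": ["A"]})


class TestShuffleRegions:
    REGIONS = pd.DataFrame(
        {"chrom": ["1", "1", "2"], "start": [0, 500_000, 100_000],
         "end": [100_000, 600_000, 130_000]}
    )
    LENGTHS = {"1": 2_000_000, "2": 1_000_000}

    def test_lengths_and_chromosomes_preserved(self):
        rng = np.random.default_rng(0)
        out = shuffle_regions(self.REGIONS, self.LENGTHS, rng)
        assert out["chrom"].tolist() == self.REGIONS["chrom"].tolist()
        assert ((out["end"] - out["start"]).to_numpy()
                == (self.REGIONS["end"] - self.REGIONS["start"]).to_numpy()).all()
        for c, sub in out.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_start_positions_uniform(self):
        """Chi-square goodness of fit on a 2-bin partition of the chromosome
        over many shuffles."""
        from scipy.stats import chisquare

        rng = np.random.default_rng(1)
        region = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1000]})
        starts = np.array(
            [
                shuffle_regions(region, {"1": 1_001_000}, rng)["start"].iloc[0]
                for _ in range(10_000)
            ]
        )
        counts = [np.sum(starts < 500_000), np.sum(starts >= 500_000)]
        assert chisquare(counts).pvalue > 0.01


@pytest.fixture(scope="module")
def toy():
    chrom_lengths = {"1": 10_000_000, "2": 8_000_000}
    genes, annot, onto = generate_toy_annotation(chrom_lengths, 80, 3, 12, seed=6)
    return chrom_lengths, genes, Ontology.from_tables(annot, onto)


class TestPermutationPvalues:
    def test_p_perm_formula_and_bounds(self, toy):
        chrom_lengths, genes, ontology = toy
        regions = pd.DataFrame(
            {"chrom": ["1", "2"], "start": [1_000_000, 2_000_000],
             "end": [1_200_000, 2_150_000]}
        )
        res = permutation_pvalues(regions, genes, ontology, chrom_lengths,
                                  n_permutations=50, seed=0)
        assert np.allclose(res["p_perm"], (res["x_perm"] + 1) / 51)
        assert (res["p_perm"] >= 1 / 51 - 1e-12).all()
        assert (res["p_perm"] <= 1.0 + 1e-12).all()

    def test_null_calibration_about_five_percent(self, toy):
        """With a random region set, ~5% of terms reach p_perm < 0.05."""
        chrom_lengths, genes, ontology = toy
        rng = np.random.default_rng(7)
        flags, total = 0, 0
        for s in range(8):
            starts = rng.integers(0, 9_000_000, size=3)
            regions = pd.DataFrame(
                {"chrom": ["1"] * 3, "start": starts, "end": starts + 150_000}
            )
            res = permutation_pvalues(regions, genes, ontology, chrom_lengths,
                                      n_permutations=100, seed=s)
            flags += int((res["p_perm"] < 0.05).sum())
            total += len(res)
        # binomial 99% CI around 5% of `total` terms
        from scipy.stats import binomtest

        assert binomtest(flags, total, 0.05).pvalue > 0.001

    def test_invalid_permutation_count(self, toy):
        chrom_lengths, genes, ontology = toy
        regions = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1000]})
        with pytest.raises(ValueError):
            permutation_pvalues(regions, genes, ontology, chrom_lengths,
                                n_permutations=0)


class TestFilterEnrichedTerms:
    def test_locus_and_gene_support_rules(self):
        res = pd.DataFrame(
            {
                "term": ["a", "b", "c", "d"],
                "p_perm": [0.01, 0.01, 0.01, 0.2],
                "n_loci": [3, 1, 2, 5],
                "n_genes": [4, 5, 1, 5],
            }
        )
        kept = filter_enriched_terms(res, alpha=0.05)
        assert kept["term"].tolist() == ["a"]


def test_p_perm_ties_count_toward_x_perm():
    """When every shuffle reproduces the observed gene set (region length =
    chromosome length), each permutation p ties the observed p, ties count
    (conservatively), and p_perm = (N+1)/(N+1) = 1."""
    genes = pd.DataFrame(
        {"chrom": ["1"], "start": [100], "end": [200], "gene": ["g1"],
         "score": [0], "strand": ["+"]}
    )
    onto = _ontology([("A", "root")], {"g1": ["A", "root"]})
    regions = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1000]})
    res = permutation_pvalues(regions, genes, onto, {"1": 1000},
                              n_permutations=20, seed=0)
    assert (res["x_perm"] == 20).all()
    assert np.allclose(res["p_perm"], 1.0)
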
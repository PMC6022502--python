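"""Gene-set enrichment near candidate regions, permutation-calibrated.

Genes within 50 kb of a candidate region form the test set. Each GO term is
scored with the parent-child over-representation test (Grossmann et al.
2007, union variant): the hypergeometric upper-tail probability of drawing
at least the observed number of the term's genes when sampling the test
genes that hit the union of the term's parents' gene sets. Because genomic
clustering, gene length and annotation structure distort raw parent-child
p-values, they are calibrated by permutation: the candidate intervals are
shuffled N times (length- and chromosome-preserving, non-overlapping), the
parent-child test is recomputed on each shuffled gene set, and

    p_perm = (X_perm + 1) / (N + 1)

where X_perm counts permutations whose p-value is <= the observed one (ties
count, and the +1s keep p_perm in [1/(N+1), 1]). Final reported terms must
have p_perm < alpha, support from more than one locus, and more than one
gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "Ontology",
    "genes_near_regions",
    "parent_child_test",
    "shuffle_regions",
    "permutation_pvalues",
    "filter_enriched_terms",
]


@dataclass
class Ontology:
    """Rooted DAG of terms with ancestor-propagated gene annotations."""

    graph: nx.DiGraph  # edges child -> parent
    term_genes: dict[str, frozenset] = field(default_factory=dict)

    @classmethod
    def from_tables(cls, annotations: pd.DataFrame, parents: pd.DataFrame) -> "Ontology":
        """Build from (gene, term) and (child, parent) tables; direct
        annotations are propagated to every ancestor term."""
        g = nx.DiGraph()
        for row in parents.itertuples(index=False):
            g.add_edge(row.child, row.parent)
        for t in pd.unique(annotations["term"]):
            g.add_node(t)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology parent links contain a cycle")
        direct: dict[str, set] = {}
        for row in annotations.itertuples(index=False):
            direct.setdefault(row.term, set()).add(row.gene)
        term_genes: dict[str, set] = {t: set(direct.get(t, ())) for t in g.nodes}
        # propagate up: children before parents
        for t in nx.topological_sort(g):
            for parent in g.successors(t):
                term_genes[parent] |= term_genes[t]
        return cls(graph=g, term_genes={t: frozenset(s) for t, s in term_genes.items()})

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))

    @property
    def roots(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)


def genes_near_regions(
    regions: pd.DataFrame, genes: pd.DataFrame, flank: int = 50_000
) -> pd.DataFrame:
    """Genes overlapping or within ``flank`` bp of any region.

    Returns one row per included gene with ``n_loci`` (count of supporting
    regions) and the supporting region indices.
    """
    gchrom = genes["chrom"].to_numpy(dtype=object)
    gstart = genes["start"].to_numpy(dtype=np.int64)
    gend = genes["end"].to_numpy(dtype=np.int64)
    hit_lists: list[list[int]] = [[] for _ in range(len(genes))]
    regions = regions.reset_index(drop=True)
    for ridx, (rc, rs, re) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        mask = (gchrom == rc) & (gstart < re + flank) & (gend > rs - flank)
        for gi in np.flatnonzero(mask):
            hit_lists[gi].append(ridx)
    out = [
        {
            "gene": genes["gene"].iat[gi],
            "chrom": gchrom[gi],
            "start": int(gstart[gi]),
            "end": int(gend[gi]),
            "n_loci": len(hits),
            "loci": tuple(hits),
        }
        for gi, hits in enumerate(hit_lists)
        if hits
    ]
    return pd.DataFrame(
        out, columns=["gene", "chrom", "start", "end", "n_loci", "loci"]
    )


def parent_child_test(
    test_genes, ontology: Ontology, universe
) -> pd.DataFrame:
    """Parent-child (union) over-representation p-value per term.

    For term t with parent gene-set union U (within the universe): p is the
    hypergeometric upper tail of seeing >= k genes of t among the test genes
    that fall in U. Root terms get p = 1 (they condition on themselves);
    terms whose parents annotate no universe gene are skipped.
    """
    test = frozenset(test_genes)
    universe = frozenset(universe)
    if not test <= universe:
        raise ValueError("test genes must be a subset of the universe")
    rows = []
    for t in ontology.terms:
        genes_t = ontology.term_genes.get(t, frozenset()) & universe
        k = len(genes_t & test)
        parents = ontology.parents(t)
        if not parents:
            rows.append({"term": t, "p": 1.0, "k": k, "n_genes_term": len(genes_t)})
            continue
        pa_union = frozenset().union(
            *(ontology.term_genes.get(p, frozenset()) for p in parents)
        ) & universe
        if not pa_union:
            continue  # p undefined
        m = len(genes_t & pa_union)
        n_draw = len(test & pa_union)
        p = float(hypergeom.sf(k - 1, len(pa_union), m, n_draw))
        rows.append({"term": t, "p": min(p, 1.0), "k": k, "n_genes_term": len(genes_t)})
    return pd.DataFrame(rows, columns=["term", "p", "k", "n_genes_term"])


def shuffle_regions(
    regions: pd.DataFrame,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Random length- and chromosome-preserving placement of regions.

    Start positions are uniform on the chromosome; placements overlapping an
    already-placed shuffled region are rejected and retried.
    """
    placed: dict[str, list[tuple[int, int]]] = {}
    rows = []
    for row in regions.itertuples(index=False):
        length = int(row.end - row.start)
        limit = chrom_lengths[row.chrom] - length
        if limit < 0:
            raise ValueError(f"region longer than chromosome {row.chrom!r}")
        for _ in range(max_tries):
            start = int(rng.integers(0, limit + 1))
            end = start + length
            if all(start >= e or end <= s for s, e in placed.get(row.chrom, ())):
                break
        else:
            raise RuntimeError("could not place a shuffled region without overlap")
        placed.setdefault(row.chrom, []).append((start, end))
        rows.append({"chrom": row.chrom, "start": start, "end": end})
    return pd.DataFrame(rows)


def permutation_pvalues(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    ontology: Ontology,
    chrom_lengths: dict[str, int],
    n_permutations: int = 1000,
    seed: int = 0,
    flank: int = 50_000,
    universe=None,
) -> pd.DataFrame:
    """Permutation-calibrated enrichment for every testable term.

    Returns per term: observed parent-child p, X_perm, N, p_perm =
    (X_perm + 1)/(N + 1), the number of supporting test genes and distinct
    supporting loci.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if universe is None:
        universe = frozenset(genes["gene"])
    hits = genes_near_regions(regions, genes, flank=flank)
    test = frozenset(hits["gene"])
    observed = parent_child_test(test, ontology, universe)

    # per-term supporting gene/locus counts
    gene_loci = dict(zip(hits["gene"], hits["loci"]))
    n_genes_sup, n_loci_sup = {}, {}
    for t in observed["term"]:
        tg = ontology.term_genes.get(t, frozenset()) & test
        n_genes_sup[t] = len(tg)
        n_loci_sup[t] = len(set().union(*(gene_loci[g] for g in tg)) if tg else set())

    rng = np.random.default_rng(seed)
    order = observed["term"].tolist()
    obs_p = observed.set_index("term")["p"]
    x_perm = pd.Series(0, index=order, dtype=int)
    for _ in range(n_permutations):
        shuffled = shuffle_regions(regions, chrom_lengths, rng)
        perm_test = frozenset(genes_near_regions(shuffled, genes, flank=flank)["gene"])
        perm = parent_child_test(perm_test, ontology, universe).set_index("term")["p"]
        common = perm.index.intersection(obs_p.index)
        leq = perm.loc[common] <= obs_p.loc[common]
        x_perm.loc[common[leq]] += 1

    out = observed.copy()
    out["x_perm"] = x_perm.loc[order].to_numpy()
    out["n_permutations"] = n_permutations
    out["p_perm"] = (out["x_perm"] + 1) / (n_permutations + 1)
    out["n_genes"] = [n_genes_sup[t] for t in order]
    out["n_loci"] = [n_loci_sup[t] for t in order]
    return out


def filter_enriched_terms(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Final enriched set: p_perm < alpha, > 1 supporting locus, > 1 gene.

    The locus rule drops terms driven by a single clustered region; the gene
    rule drops terms whose signal is one gene spanned by several loci.
    """
    keep = (
        (results["p_perm"] < alpha)
        & (results["n_loci"] >= 2)
        & (results["n_genes"] >= 2)
    )
    return results[keep].reset_index(drop=True)
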
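"""Protein-protein interaction linkage and gene-set enrichment.

The interaction graph is consumed as an edge list (never queried from a live
database); a candidate gene is "linked" when, inside the subgraph induced by
the seed genes plus the candidate set, it falls in a connected component that
contains at least one seed.  Enrichment of a gene set in a pathway is a plain
hypergeometric over-representation test with BH adjustment across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats

from .burden import bh_fdr

__all__ = ["InteractionGraph", "is_linked", "enrichment_test", "enrichment_tests"]

DEFAULT_MIN_SCORE = 0.4  # the customary "medium confidence" edge threshold


@dataclass
class InteractionGraph:
    """Undirected interaction graph plus the seed genes of interest."""

    graph: nx.Graph
    seed_genes: tuple

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        seed_genes: Sequence[str],
        min_score: float = DEFAULT_MIN_SCORE,
    ) -> "InteractionGraph":
        """Build from (geneA, geneB, score) triples.

        Self-loops and edges below ``min_score`` are dropped at load time.
        Seed genes are added as nodes even when they have no retained edge.
        """
        g = nx.Graph()
        for a, b, *rest in edges:
            score = float(rest[0]) if rest else 1.0
            if a == b:
                continue
            if score < min_score:
                continue
            g.add_edge(a, b, score=score)
        g.add_nodes_from(seed_genes)
        return cls(graph=g, seed_genes=tuple(seed_genes))


def is_linked(graph: InteractionGraph, gene: str, candidate_set: Sequence[str]) -> bool:
    """Is ``gene`` connected to the seed network?

    Within the subgraph induced by seeds union candidates, True iff the gene
    sits in a connected component containing at least one seed and has at
    least one edge (an isolated node is never linked).  A path through other
    candidate genes counts.  A gene absent from the graph is not linked —
    absence of evidence, reported as False.
    """
    nodes = set(graph.seed_genes) | set(candidate_set) | {gene}
    sub = graph.graph.subgraph(n for n in nodes if n in graph.graph)
    if gene not in sub or sub.degree(gene) == 0:
        return False
    seeds = set(graph.seed_genes)
    component = nx.node_connected_component(sub, gene)
    return bool(component & seeds)


def enrichment_test(
    gene_set: Sequence[str],
    pathway_members: Sequence[str],
    universe: Sequence[str],
) -> float:
    """Hypergeometric over-representation p-value of gene_set in a pathway.

    P(X >= k) where k is the overlap, drawing len(gene_set) genes from a
    universe containing len(pathway in universe) pathway members.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    genes = set(gene_set)
    if not genes <= uni:
        raise ValueError("gene_set must be a subset of the universe")
    members = set(pathway_members) & uni
    k = len(genes & members)
    return float(stats.hypergeom.sf(k - 1, len(uni), len(members), len(genes)))


def enrichment_tests(
    pathways: Mapping[str, Sequence[str]],
    gene_set: Sequence[str],
    universe: Sequence[str],
) -> dict:
    """Per-pathway hypergeometric p with BH-FDR q across the pathways."""
    names = list(pathways)
    p = [enrichment_test(gene_set, pathways[name], universe) for name in names]
    q = bh_fdr(p)
    return {name: (float(pv), float(qv)) for name, pv, qv in zip(names, p, q)}
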
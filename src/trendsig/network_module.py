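"""Interaction-network mapping and disease gene-module extraction.

Signature genes are mapped onto a user-supplied protein-protein interaction
edge list (STRING-export-like: two gene columns plus a confidence score).
The disease gene module is defined as the largest connected component of the
induced subgraph; association between module sub-clusters and signature
membership is tested with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .errors import ValidationError


@dataclass(frozen=True)
class Module:
    """A connected gene module: sorted member tuple plus its edge subset."""

    members: tuple
    edges: tuple

    @property
    def size(self) -> int:
        return len(self.members)


def build_graph(edges: pd.DataFrame, min_score: float = 0.4) -> nx.Graph:
    """Undirected graph from an edge list, dropping self-loops, collapsing
    duplicate pairs (keeping the max score) and filtering ``score >= min_score``."""
    g = nx.Graph()
    kept = edges[edges["score"] >= min_score]
    for row in kept.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(row.score))
        else:
            g.add_edge(a, b, score=float(row.score))
    return g


def map_to_network(genes, edges: pd.DataFrame, min_score: float = 0.4):
    """Induce the subgraph of ``genes`` on the filtered interaction network.

    Returns ``(subgraph, unmapped)`` where unmapped lists genes absent from
    the filtered edge list (sorted).
    """
    network = build_graph(edges, min_score=min_score)
    genes = [str(g) for g in genes]
    present = [g for g in genes if g in network]
    unmapped = sorted(set(genes) - set(present))
    return network.subgraph(present).copy(), unmapped


def largest_connected_component(subgraph: nx.Graph) -> Module:
    """The maximum-cardinality connected component as a Module.

    Ties on size are broken by the lexicographically smallest sorted member
    list; an empty graph yields an empty module.
    """
    comps = [tuple(sorted(c)) for c in nx.connected_components(subgraph)]
    if not comps:
        return Module(members=(), edges=())
    comps.sort(key=lambda c: (-len(c), c))
    members = comps[0]
    sub = subgraph.subgraph(members)
    edges = tuple(sorted(tuple(sorted(e)) for e in sub.edges()))
    return Module(members=members, edges=edges)


def module_fraction(module: Module | int, mapped_genes) -> float:
    """Percentage of mapped genes inside the module, half-up to 1 decimal."""
    size = module.size if isinstance(module, Module) else int(module)
    n = len(mapped_genes) if not isinstance(mapped_genes, int) else mapped_genes
    if n == 0:
        raise ValidationError("no mapped genes: fraction undefined")
    if size > n:
        raise ValidationError("module larger than mapped gene set")
    return round_half_up(100.0 * size / n, 1)


def cluster_association_test(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities no larger than the observed table's.
    """
    t = pd.DataFrame(table).to_numpy()
    if t.shape != (2, 2):
        raise ValidationError("need a 2x2 table")
    if (t < 0).any() or t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValidationError("counts must be non-negative with positive margins")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)
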
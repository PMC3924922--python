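"""Bipartite trait-pathway network, weighted projection, and statistics.

Traits and pathways form a two-mode graph: a trait is linked to every
pathway reached through at least one of its genes.  Projecting onto the
trait side links two traits whenever their pathway sets intersect, with
edge weight ω_ij equal to the number of shared pathways — the phenotype
network proper.  The symmetric projection onto the pathway side links
pathways sharing a trait.

Graphs are plain :class:`networkx.Graph` objects.  Bipartite graphs
carry a ``kind`` node attribute ("trait"/"pathway"); weighted graphs
carry integer (or, in general, positive real) ``weight`` edge
attributes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
from networkx.algorithms import bipartite

from .associations import TraitPathwayMap

logger = logging.getLogger(__name__)


class NetBuildError(ValueError):
    pass


def build_bipartite(tp_map: TraitPathwayMap) -> nx.Graph:
    """Build the two-mode trait-pathway graph from a trait→pathway map.

    One edge per (trait, pathway) membership.  Traits with an empty
    pathway set are excluded (they would be isolates on the trait side);
    pathway nodes only exist through memberships, so none is isolated.
    """
    if not tp_map.traits:
        raise NetBuildError("empty trait-pathway map")
    g = nx.Graph()
    for trait, pathways in tp_map.pathway_sets.items():
        if not pathways:
            continue
        g.add_node(trait, kind="trait", bipartite=0)
        for pw in pathways:
            g.add_node(pw, kind="pathway", bipartite=1)
            g.add_edge(trait, pw)
    if g.number_of_nodes() == 0:
        raise NetBuildError("no trait has any pathway annotation")
    n_traits = sum(1 for _, k in g.nodes(data="kind") if k == "trait")
    logger.info("bipartite network: %d traits, %d pathways, %d edges",
                n_traits, g.number_of_nodes() - n_traits, g.number_of_edges())
    return g


def trait_nodes(bn: nx.Graph) -> set[str]:
    return {n for n, k in bn.nodes(data="kind") if k == "trait"}


def pathway_nodes(bn: nx.Graph) -> set[str]:
    return {n for n, k in bn.nodes(data="kind") if k == "pathway"}


def project(bn: nx.Graph, side: str = "trait") -> nx.Graph:
    """One-mode projection with shared-neighbour-count edge weights.

    Two nodes of the chosen side are linked iff they share at least one
    neighbour on the other side; the weight is the number of shared
    neighbours (shared pathways for the trait projection).  Nodes with
    no overlap partner remain as isolates until :func:`remove_isolates`.
    """
    if side not in ("trait", "pathway"):
        raise NetBuildError(f"unknown projection side {side!r}")
    keep = trait_nodes(bn) if side == "trait" else pathway_nodes(bn)
    proj = bipartite.weighted_projected_graph(bn, keep)
    # insert in sorted order so downstream iteration (and float
    # accumulation) is reproducible across processes
    out = nx.Graph()
    out.add_nodes_from(sorted(keep, key=str))
    out.add_weighted_edges_from(
        sorted(((u, v, d["weight"]) for u, v, d in proj.edges(data=True)),
               key=lambda e: (str(e[0]), str(e[1]))))
    return out


def remove_isolates(net: nx.Graph) -> nx.Graph:
    """Drop degree-0 nodes; the edge set is untouched."""
    isolates = list(nx.isolates(net))
    out = net.copy()
    out.remove_nodes_from(isolates)
    if isolates:
        logger.info("removed %d isolate nodes (%d remain)",
                    len(isolates), out.number_of_nodes())
    return out


@dataclass(frozen=True)
class NetSummary:
    """Descriptive statistics of a weighted network.

    Clustering and path length are computed on topology alone (weights
    ignored).  ``avg_path_length`` is taken over the largest connected
    component, the only component-robust finite definition; it is None
    for graphs with fewer than two nodes or no edges.
    """

    n_nodes: int
    n_edges: int
    mean_degree: float
    degree_distribution: Mapping[int, float]
    avg_clustering: float
    avg_path_length: float | None
    total_weight: float
    strength: Mapping[str, float]

    def as_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "avg_clustering": self.avg_clustering,
            "avg_path_length": self.avg_path_length,
            "total_weight": self.total_weight,
        }
        return d


def summarize(net: nx.Graph) -> NetSummary:
    """Compute the descriptive statistics used throughout the pipeline."""
    n = net.number_of_nodes()
    m = net.number_of_edges()
    degree_counts = Counter(d for _, d in net.degree())
    pk = {k: c / n for k, c in sorted(degree_counts.items())} if n else {}
    cc = nx.average_clustering(net) if n else 0.0
    apl: float | None = None
    if n >= 2 and m >= 1:
        largest = max(nx.connected_components(net), key=len)
        if len(largest) >= 2:
            apl = nx.average_shortest_path_length(net.subgraph(largest))
    strength = {u: float(s) for u, s in net.degree(weight="weight")}
    return NetSummary(
        n_nodes=n,
        n_edges=m,
        mean_degree=(2 * m / n) if n else 0.0,
        degree_distribution=pk,
        avg_clustering=cc,
        avg_path_length=apl,
        total_weight=float(net.size(weight="weight")),
        strength=strength,
    )


def explain_edge(tp_map: TraitPathwayMap, t1: str, t2: str
                 ) -> tuple[frozenset[str], frozenset[str]]:
    """Genes and pathways two traits have in common.

    The shared-pathway count equals the projection weight ω(t1, t2)
    exactly (or 0 when no edge exists).  ``t1 == t2`` degenerately
    returns the trait's own full sets.
    """
    for t in (t1, t2):
        if t not in tp_map.gene_sets:
            raise KeyError(f"unknown trait {t!r}")
    shared_genes = tp_map.gene_sets[t1] & tp_map.gene_sets[t2]
    shared_pathways = tp_map.pathway_sets[t1] & tp_map.pathway_sets[t2]
    return frozenset(shared_genes), frozenset(shared_pathways)


# ---------------------------------------------------------------------------
# import/export

def write_net(net: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a weighted network as edge-list TSV, GraphML, or GML."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "tsv":
        # canonical orientation and order so equal graphs give equal files
        rows = [(*sorted((str(u), str(v))), d.get("weight", 1))
                for u, v, d in net.edges(data=True)]
        df = pd.DataFrame(sorted(rows), columns=["node_i", "node_j", "weight"])
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "gml":
        nx.write_gml(net, path)
    else:
        raise NetBuildError(f"unknown network format {fmt!r}")


def read_net(path: str | Path, fmt: str | None = None) -> nx.Graph:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"node_i": str, "node_j": str})
        g = nx.Graph()
        for u, v, w in df.itertuples(index=False):
            g.add_edge(str(u), str(v), weight=float(w) if not float(w).is_integer()
                       else int(w))
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gml":
        return nx.read_gml(path)
    raise NetBuildError(f"unknown network format {fmt!r}")
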
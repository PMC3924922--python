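"""Multiscale information-backbone extraction with the disparity filter.

Dense weighted networks hide their structure: a single global weight
threshold keeps only edges attached to the few strongest hubs and
disconnects everything else.  The disparity filter instead tests each
edge *locally*.  For a node of degree k with strength s_i (sum of its
incident weights), the normalised weight of an incident edge is
p_ij = ω_ij / s_i, and under the null hypothesis that the node's unit
strength is split uniformly at random among its k edges, the probability
of a normalised weight at least as large as p_ij is

    α_ij = (1 - p_ij)^(k-1)

(the closed form of 1 - (k-1)∫₀^{p} (1-x)^{k-2} dx).  An edge is
significant from node i's side when α_ij falls below the chosen level α.
Each edge gets two independent values, α_ij and α_ji; the OR rule keeps
the edge when either side is significant, the stricter AND rule requires
both.  Degree and strength are always taken from the unfiltered input
network (one-shot filter).

Degree-1 nodes carry their whole strength on one edge; the null can
never be rejected from their side, so α_ij is set to 1 there.  Under AND
such edges never survive, under OR they survive only via the partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .netbuild import remove_isolates, summarize

logger = logging.getLogger(__name__)


class BackboneError(ValueError):
    pass


def disparity_alpha(p: float, k: int) -> float:
    """Significance α_ij = (1 - p)^(k - 1) of one edge seen from one node.

    ``p`` is the normalised edge weight from that node's side and ``k``
    the node's degree.  For k = 1 the null is never rejected (α = 1).
    """
    if k < 1:
        raise BackboneError("degree must be >= 1")
    if k == 1:
        return 1.0
    return (1.0 - p) ** (k - 1)


@dataclass(frozen=True)
class EdgeSignificance:
    """Directed per-edge normalised weights and disparity p-values.

    ``p[(i, j)]`` is ω_ij / s_i; ``alpha[(i, j)]`` is the significance
    of edge (i, j) from node i's side.  Both directions are stored.
    """

    p: Mapping[tuple[str, str], float]
    alpha: Mapping[tuple[str, str], float]


@dataclass(frozen=True)
class BackboneConfig:
    """Significance level and combination rule for the filter."""

    alpha: float
    rule: str = "AND"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise BackboneError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.rule.upper() not in ("AND", "OR"):
            raise BackboneError(f"rule must be AND or OR, got {self.rule!r}")
        object.__setattr__(self, "rule", self.rule.upper())


def edge_significance(net: nx.Graph) -> EdgeSignificance:
    """Compute p_ij and α_ij for both directions of every edge."""
    p: dict[tuple[str, str], float] = {}
    alpha: dict[tuple[str, str], float] = {}
    degree = dict(net.degree())
    strength = dict(net.degree(weight="weight"))
    for u, v, d in net.edges(data=True):
        w = d.get("weight", 1)
        if w <= 0:
            raise BackboneError(f"non-positive weight on edge ({u!r}, {v!r})")
        for a, b in ((u, v), (v, u)):
            pij = w / strength[a]
            p[(a, b)] = pij
            alpha[(a, b)] = disparity_alpha(pij, degree[a])
    return EdgeSignificance(p=p, alpha=alpha)


def apply_filter(net: nx.Graph, sig: EdgeSignificance,
                 cfg: BackboneConfig) -> nx.Graph:
    """Keep edges whose α_ij beats the level under the AND/OR rule.

    Surviving edges retain their original weights; nodes left isolated
    by the pruning are removed (the fraction retained is still tracked
    against the unfiltered node count by :func:`sweep`).
    """
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        if (u, v) not in sig.alpha:
            raise BackboneError(f"significance table lacks edge ({u!r}, {v!r})")
        a_uv = sig.alpha[(u, v)]
        a_vu = sig.alpha[(v, u)]
        if cfg.rule == "AND":
            keep = a_uv < cfg.alpha and a_vu < cfg.alpha
        else:
            keep = a_uv < cfg.alpha or a_vu < cfg.alpha
        if keep:
            out.add_edge(u, v, **d)
    return remove_isolates(out)


def extract_backbone(net: nx.Graph, alpha: float,
                     rule: str = "AND") -> nx.Graph:
    """Convenience wrapper: significance + filter in one call."""
    return apply_filter(net, edge_significance(net), BackboneConfig(alpha, rule))


def sweep(net: nx.Graph, grid: Sequence[float],
          rule: str = "AND") -> pd.DataFrame:
    """Filter at every α in ``grid`` and chart what survives.

    Returns one row per α with the fraction of edges, non-isolated
    vertices, and total weight retained (relative to the unfiltered
    network) plus the filtered network's average clustering coefficient.
    """
    if len(grid) == 0:
        raise BackboneError("empty alpha grid")
    if any(a < 0 or a > 1 for a in grid):
        raise BackboneError("alpha grid values must lie in [0, 1]")
    n0 = net.number_of_nodes()
    m0 = net.number_of_edges()
    w0 = net.size(weight="weight")
    sig = edge_significance(net)
    rows = []
    for a in grid:
        bb = apply_filter(net, sig, BackboneConfig(a, rule))
        rows.append({
            "alpha": a,
            "frac_edges": bb.number_of_edges() / m0 if m0 else 0.0,
            "frac_vertices": bb.number_of_nodes() / n0 if n0 else 0.0,
            "frac_weight": bb.size(weight="weight") / w0 if w0 else 0.0,
            "avg_cc": nx.average_clustering(bb) if bb.number_of_nodes() else 0.0,
        })
    return pd.DataFrame(rows)


def default_grid(n: int = 201) -> list[float]:
    """Evenly spaced α values covering [0, 1]."""
    return [i / (n - 1) for i in range(n)]


def pick_alpha(table: pd.DataFrame, target_frac_edges: float) -> float:
    """α on the sweep grid whose retained-edge fraction is closest to target.

    Ties break toward the smaller (stricter) α.
    """
    if len(table) == 0:
        raise BackboneError("empty sweep table")
    t = table.sort_values("alpha", kind="stable")
    best = min(t.itertuples(index=False),
               key=lambda r: (abs(r.frac_edges - target_frac_edges), r.alpha))
    return float(best.alpha)


def global_weight_filter(net: nx.Graph, cutoff: float) -> nx.Graph:
    """Baseline filter: keep edges with ω >= cutoff, drop new isolates."""
    if cutoff < 0:
        raise BackboneError("cutoff must be >= 0")
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        if d.get("weight", 1) >= cutoff:
            out.add_edge(u, v, **d)
    return remove_isolates(out)


def match_edge_fraction(net: nx.Graph,
                        target_frac: float) -> tuple[float, float]:
    """Weight cutoff whose retained-edge fraction best approaches target
    from below.

    Returns ``(cutoff, achieved_fraction)`` where cutoff is the smallest
    observed edge weight w such that the fraction of edges with ω >= w
    is <= ``target_frac``.  With tied weights the achieved fraction can
    be well under the target; it is reported so the caller can judge.
    """
    if not 0 < target_frac <= 1:
        raise BackboneError("target_frac must be in (0, 1]")
    weights = sorted((d.get("weight", 1) for _, _, d in net.edges(data=True)),
                     reverse=True)
    m = len(weights)
    if m == 0:
        return 0.0, 0.0
    best_cut, best_frac = float("inf"), 0.0
    for i, w in enumerate(weights):
        # cutoff at w keeps every edge with weight >= w
        kept = sum(1 for x in weights if x >= w)
        frac = kept / m
        if frac <= target_frac:
            best_cut, best_frac = w, frac
        else:
            break
    if best_cut == float("inf"):
        # even the maximum weight keeps too many edges; report it anyway
        w = weights[0]
        best_cut = w
        best_frac = sum(1 for x in weights if x >= w) / m
    return float(best_cut), best_frac


def compare_filters(net: nx.Graph, df_result: nx.Graph,
                    gw_result: nx.Graph) -> dict:
    """Side-by-side statistics of two filtered networks vs the original.

    Mirrors the tabular comparison of disparity-filter and global-weight
    backbones: node/edge/weight counts with percentages of the
    unfiltered network, mean degree, clustering, and path length.
    """
    def block(g: nx.Graph, base: "nx.Graph | None" = None) -> dict:
        s = summarize(g)
        rec = {
            "n_nodes": s.n_nodes, "n_edges": s.n_edges,
            "total_weight": s.total_weight, "mean_degree": s.mean_degree,
            "avg_clustering": s.avg_clustering,
            "avg_path_length": s.avg_path_length,
        }
        if base is not None:
            b = summarize(base)
            rec["pct_nodes"] = 100.0 * s.n_nodes / b.n_nodes if b.n_nodes else 0.0
            rec["pct_edges"] = 100.0 * s.n_edges / b.n_edges if b.n_edges else 0.0
            rec["pct_weight"] = (100.0 * s.total_weight / b.total_weight
                                 if b.total_weight else 0.0)
        return rec

    return {
        "unfiltered": block(net),
        "disparity": block(df_result, net),
        "global_weight": block(gw_result, net),
    }
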
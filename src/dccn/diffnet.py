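"""Disease-exclusive differential subnetworks, ego networks and summaries.

The differential construction removes the edges shared by the two
group-specific networks; what remains — edges exclusive to one group —
isolates co-consumption relationships specific to that disease status.
Each exclusive subnetwork is the edge-induced subgraph on its exclusive
edges, carrying the weights from its source network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import DataError
from .network import CoConsumptionNetwork

logger = logging.getLogger(__name__)


@dataclass
class DifferentialNetworks:
    group_a_exclusive: nx.Graph
    group_b_exclusive: nx.Graph
    shared_edges: set[tuple[str, str]]


@dataclass
class GraphSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    clustering: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _edge_key(a, b) -> tuple:
    return (a, b) if a <= b else (b, a)


def differential(
    net_a: CoConsumptionNetwork | nx.Graph,
    net_b: CoConsumptionNetwork | nx.Graph,
) -> DifferentialNetworks:
    """Split two same-universe networks into exclusive subgraphs + shared set.

    Edge identity is the unordered food pair; weights play no role in
    membership but are carried over from the source network onto its
    exclusive subgraph.
    """
    ga = net_a.to_networkx() if hasattr(net_a, "to_networkx") else net_a
    gb = net_b.to_networkx() if hasattr(net_b, "to_networkx") else net_b
    if set(ga.nodes) != set(gb.nodes):
        only_a = sorted(set(ga.nodes) - set(gb.nodes))
        only_b = sorted(set(gb.nodes) - set(ga.nodes))
        raise DataError(
            f"node universes differ: only in A {only_a}, only in B {only_b}"
        )
    ea = {_edge_key(*e) for e in ga.edges}
    eb = {_edge_key(*e) for e in gb.edges}
    shared = ea & eb

    def exclusive(g: nx.Graph, keep: set) -> nx.Graph:
        sub = nx.Graph(group=g.graph.get("group"))
        for a, b in sorted(keep):
            sub.add_edge(a, b, **g.edges[a, b])
        return sub

    return DifferentialNetworks(
        group_a_exclusive=exclusive(ga, ea - shared),
        group_b_exclusive=exclusive(gb, eb - shared),
        shared_edges=shared,
    )


def ego_network(net, focal: str, steps: int = 2) -> nx.Graph:
    """Induced subgraph on all nodes within ``steps`` hops of ``focal``."""
    g = net.to_networkx() if hasattr(net, "to_networkx") else net
    if focal not in g:
        raise DataError(f"focal food {focal!r} not in network")
    if g.degree(focal) == 0:
        logger.warning("focal food %r is an isolate", focal)
    reach = nx.single_source_shortest_path_length(g, focal, cutoff=steps)
    return g.subgraph(reach).copy()


def summarize(graph: nx.Graph) -> GraphSummary:
    """Node/edge counts, average degree 2E/N, density, global transitivity."""
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    if n == 0:
        raise DataError("empty graph")
    if n == 1:
        return GraphSummary(1, e, 0.0, 0.0, 0.0, degenerate=True)
    return GraphSummary(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        density=2.0 * e / (n * (n - 1)),
        clustering=float(nx.transitivity(graph)),
    )


def summarize_egos(net, focals, steps: int = 2) -> dict:
    """Per-ego summaries plus arithmetic means across the focal foods."""
    per = {f: summarize(ego_network(net, f, steps)) for f in focals}
    fields = ["n_nodes", "n_edges", "average_degree", "density", "clustering"]
    means = {
        k: float(np.mean([getattr(s, k) for s in per.values()])) for k in fields
    }
    return {"per_ego": {f: s.as_dict() for f, s in per.items()}, "mean": means}


def degree_hub_threshold(graph: nx.Graph, pct: float = 0.75) -> float:
    """Degree cut for hub highlighting (linear-interpolation percentile)."""
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    return float(np.quantile(degrees, pct))
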
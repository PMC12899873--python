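"""Node centralities, z-score integration and network-role classification.

Five complementary measures per node — degree (connections), strength
(total absolute edge weight), betweenness (mediation), closeness
(position) and eigenvector (influence) — are z-standardized across the
scored nodes and averaged into a single integrated centrality, which is
the scoring weight used downstream.

Edge signs are kept on the graph but centralities operate on |weight|:
shortest-path measures use distance 1/|w| (stronger co-consumption =
closer) and the eigenvector uses the |w| adjacency of the largest
connected component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .errors import ConvergenceError, DataError

ROLE_LEVELS = ("primary_hub", "hub_food", "bridge", "connector", "peripheral")


def _power_iteration(A: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000):
    # shift by I: same Perron vector, breaks the +/-lambda tie of bipartite graphs
    A = A + np.eye(A.shape[0])
    x = np.full(A.shape[0], 1.0 / np.sqrt(A.shape[0]))
    for it in range(max_iter):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return x  # no edges; centrality undefined, caller handles
        y /= norm
        if np.abs(y - x).max() < tol:
            return y
        x = y
    raise ConvergenceError(
        f"eigenvector power iteration did not converge in {max_iter} iterations"
    )


def centralities(graph: nx.Graph, weight: str = "weight") -> pd.DataFrame:
    """Centrality table for one (sub)network.

    Returns a DataFrame indexed by node with the five raw measures, their
    z-scores (population SD; zero-variance columns -> all-zero z), the
    integrated centrality (mean of the five z columns) and the rank by
    integrated centrality (1 = highest; ties broken by node name).
    """
    if graph.number_of_nodes() == 0:
        raise DataError("empty graph")
    nodes = sorted(graph.nodes)
    weighted = any(weight in d for _, _, d in graph.edges(data=True))

    dist = nx.Graph()
    dist.add_nodes_from(nodes)
    for a, b, d in graph.edges(data=True):
        w = abs(d.get(weight, 1.0))
        if w == 0:
            raise DataError(f"zero-weight edge ({a}, {b})")
        dist.add_edge(a, b, absw=w, dist=1.0 / w if weighted else 1.0)

    degree = {v: graph.degree(v) for v in nodes}
    strength = {
        v: float(sum(abs(d.get(weight, 1.0)) for _, _, d in graph.edges(v, data=True)))
        for v in nodes
    }
    betweenness = nx.betweenness_centrality(dist, weight="dist", normalized=True)
    closeness = {}
    for v in nodes:
        lengths = nx.single_source_dijkstra_path_length(dist, v, weight="dist")
        lengths.pop(v, None)
        closeness[v] = len(lengths) / sum(lengths.values()) if lengths else 0.0

    eigenvector = dict.fromkeys(nodes, 0.0)
    components = sorted(nx.connected_components(dist), key=lambda c: (-len(c), sorted(c)))
    comp = sorted(components[0]) if components else []
    if len(comp) > 1:
        A = nx.to_numpy_array(dist, nodelist=comp, weight="absw")
        vec = np.abs(_power_iteration(A))
        vec = vec / vec.max() if vec.max() > 0 else vec
        eigenvector.update(dict(zip(comp, vec)))
    elif len(comp) == 1:
        eigenvector[comp[0]] = 0.0

    table = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "strength": pd.Series(strength),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
            "eigenvector": pd.Series(eigenvector),
        }
    ).loc[nodes]

    for col in ("degree", "strength", "betweenness", "closeness", "eigenvector"):
        v = table[col].to_numpy()
        sd = v.std()  # population SD; near-zero spread counts as constant
        if sd <= 1e-12 * max(1.0, float(np.abs(v).max())):
            table["z_" + col] = 0.0
        else:
            table["z_" + col] = (v - v.mean()) / sd
    zcols = [c for c in table.columns if c.startswith("z_")]
    table["integrated"] = table[zcols].mean(axis=1)
    # rank 1 = highest integrated; ties broken lexicographically by node name
    ranked = sorted(table.index, key=lambda v: (-table.at[v, "integrated"], v))
    table["rank"] = pd.Series({v: i + 1 for i, v in enumerate(ranked)})
    return table


def classify_roles(table: pd.DataFrame) -> pd.Series:
    """Hierarchical network-role labels from a centrality table.

    Order of rules: rank 1 with eigenvector >= 0.8 -> primary_hub;
    ranks 2–3 -> hub_food; betweenness >= 0.15 -> bridge; degree >= 2 ->
    connector; else peripheral.
    """
    needed = {"rank", "eigenvector", "betweenness", "degree"}
    missing = needed - set(table.columns)
    if missing:
        raise DataError(f"centrality table missing columns: {sorted(missing)}")

    def role(row) -> str:
        if row["rank"] == 1 and row["eigenvector"] >= 0.8:
            return "primary_hub"
        if row["rank"] in (2, 3):
            return "hub_food"
        if row["betweenness"] >= 0.15:
            return "bridge"
        if row["degree"] >= 2:
            return "connector"
        return "peripheral"

    return table.apply(role, axis=1).rename("role")


def centrality_weights(table: pd.DataFrame) -> dict[str, float]:
    """Food -> integrated centrality map, the scoring weights."""
    return {str(k): float(v) for k, v in table["integrated"].items()}
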
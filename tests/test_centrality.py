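import networkx as nx
import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from dccn.centrality import centralities, centrality_weights, classify_roles
from dccn.errors import DataError
from dccn.reference import reference_centrality_table


def brute_betweenness(graph: nx.Graph, dist_attr: str) -> dict:
    """All-pairs Dijkstra with explicit shortest-path counting.

    Independent of the Brandes implementation: distances come from
    scipy.sparse.csgraph, path counts from a DP over nodes ordered by
    distance, and pair dependencies are accumulated directly.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for a, b, d in graph.edges(data=True):
        i, j = idx[a], idx[b]
        rows += [i, j]
        cols += [j, i]
        vals += [d[dist_attr]] * 2
    W = csr_matrix((vals, (rows, cols)), shape=(n, n))
    D = dijkstra(W, directed=False)

    adj = [[] for _ in range(n)]
    for a, b, d in graph.edges(data=True):
        adj[idx[a]].append((idx[b], d[dist_attr]))
        adj[idx[b]].append((idx[a], d[dist_attr]))

    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(D[s])
        sigma[s, s] = 1.0
        for v in order:
            if v == s or not np.isfinite(D[s, v]):
                continue
            total = 0.0
            for u, w in adj[v]:
                if np.isfinite(D[s, u]) and abs(D[s, u] + w - D[s, v]) < 1e-9:
                    total += sigma[s, u]
            sigma[s, v] = total

    bc = dict.fromkeys(nodes, 0.0)
    for si in range(n):
        for ti in range(si + 1, n):
            if not np.isfinite(D[si, ti]) or sigma[si, ti] == 0:
                continue
            for vi in range(n):
                if vi in (si, ti):
                    continue
                if abs(D[si, vi] + D[vi, ti] - D[si, ti]) < 1e-9:
                    bc[nodes[vi]] += sigma[si, vi] * sigma[vi, ti] / sigma[si, ti]
    norm = (n - 1) * (n - 2) / 2.0
    return {v: b / norm for v, b in bc.items()}


def star(k: int = 4) -> nx.Graph:
    g = nx.Graph()
    for i in range(k):
        g.add_edge("hub", f"leaf{i}")
    return g


class TestClosedForms:
    def test_unit_star(self):
        t = centralities(star())
        assert t.at["hub", "degree"] == 4
        assert t.at["hub", "betweenness"] == pytest.approx(1.0)
        assert t.at["hub", "eigenvector"] == pytest.approx(1.0, abs=1e-9)
        assert t.at["leaf0", "eigenvector"] == pytest.approx(0.5, abs=1e-9)
        assert t.at["hub", "closeness"] == pytest.approx(1.0)
        assert t.at["leaf0", "closeness"] == pytest.approx(4.0 / 7.0)
        assert t.at["hub", "rank"] == 1

    def test_path_betweenness(self):
        g = nx.path_graph(5)
        t = centralities(g)
        # middle node mediates 4 of the 6 pairs, its neighbors 3
        assert t.at[2, "betweenness"] == pytest.approx(4 / 6)
        assert t.at[1, "betweenness"] == pytest.approx(3 / 6)
        assert t.at[0, "betweenness"] == 0.0

    def test_cycle_is_centrality_uniform(self):
        t = centralities(nx.cycle_graph(5))
        for col in ("degree", "betweenness", "closeness", "eigenvector",
                    "strength"):
            assert t[col].nunique() == 1
            assert (t["z_" + col] == 0.0).all()
        assert (t["integrated"] == 0.0).all()

    def test_weighted_path_reduces_to_unweighted_on_unit_weights(self):
        g = nx.path_graph(4)
        gw = nx.Graph()
        for a, b in g.edges:
            gw.add_edge(a, b, weight=1.0)
        a, b = centralities(g), centralities(gw)
        for col in ("betweenness", "closeness", "eigenvector"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-9)


@pytest.fixture(scope="module")
def random_weighted():
    rng = np.random.default_rng(12)
    g = nx.gnp_random_graph(20, 0.25, seed=42)
    for a, b in g.edges:
        g.edges[a, b]["weight"] = float(rng.uniform(0.2, 1.0))
        g.edges[a, b]["dist"] = 1.0 / g.edges[a, b]["weight"]
    return g


class TestAgainstOracles:
    def test_betweenness_matches_path_counting(self, random_weighted):
        t = centralities(random_weighted)
        oracle = brute_betweenness(random_weighted, "dist")
        for v in random_weighted.nodes:
            assert t.at[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)

    def test_eigenvector_matches_dense_eigendecomposition(self, random_weighted):
        t = centralities(random_weighted)
        comp = max(nx.connected_components(random_weighted), key=len)
        sub = sorted(comp)
        A = nx.to_numpy_array(random_weighted, nodelist=sub, weight="weight")
        A = np.abs(A)
        w, V = np.linalg.eigh(A)
        lead = np.abs(V[:, np.argmax(w)])
        lead /= lead.max()
        for v, x in zip(sub, lead):
            assert t.at[v, "eigenvector"] == pytest.approx(x, abs=1e-8)


class TestInvariances:
    def _graph(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.3, seed=7)
        for a, b in g.edges:
            g.edges[a, b]["weight"] = float(rng.choice([-1, 1])
                                            * rng.uniform(0.2, 0.9))
        return g

    def test_permutation_equivariance(self):
        g = self._graph()
        mapping = {v: f"n{(v * 7) % 12:02d}" for v in g.nodes}
        t1 = centralities(g)
        t2 = centralities(nx.relabel_nodes(g, mapping))
        for v in g.nodes:
            for col in ("degree", "strength", "betweenness", "closeness",
                        "eigenvector", "integrated"):
                assert t1.at[v, col] == pytest.approx(t2.at[mapping[v], col],
                                                      abs=1e-9)

    def test_positive_rescaling_of_weights(self):
        g = self._graph()
        g2 = g.copy()
        for a, b in g2.edges:
            g2.edges[a, b]["weight"] *= 3.7
        t1, t2 = centralities(g), centralities(g2)
        np.testing.assert_allclose(t1["degree"], t2["degree"])
        np.testing.assert_allclose(t1["betweenness"], t2["betweenness"],
                                   atol=1e-9)
        np.testing.assert_allclose(t1["eigenvector"], t2["eigenvector"],
                                   atol=1e-9)
        np.testing.assert_allclose(t2["strength"], 3.7 * t1["strength"])
        for col in ("z_degree", "z_strength", "z_betweenness", "z_closeness",
                    "z_eigenvector", "integrated"):
            np.testing.assert_allclose(t1[col], t2[col], atol=1e-9)
        assert (t1["closeness"].rank() == t2["closeness"].rank()).all()

    def test_z_columns_standardized(self):
        t = centralities(self._graph())
        for col in [c for c in t.columns if c.startswith("z_")]:
            v = t[col].to_numpy()
            assert abs(v.mean()) < 1e-9
            if v.std() > 0:
                assert v.std() == pytest.approx(1.0, abs=1e-9)


class TestRoles:
    def test_reference_table_roles_reproduced(self):
        """The published role labels follow from the published centralities."""
        ref = reference_centrality_table()
        for net, sub in ref.groupby("network"):
            got = classify_roles(sub.set_index("food"))
            assert got.tolist() == sub["role"].tolist()

    @pytest.mark.parametrize(
        "rank,eig,betw,deg,expected",
        [
            (1, 1.0, 0.0, 5, "primary_hub"),
            (1, 0.5, 0.0, 5, "connector"),  # rank 1, weak eigenvector: falls through
            (4, 0.2, 0.156, 4, "bridge"),
            (4, 0.2, 0.127, 2, "connector"),
            (6, 0.1, 0.01, 1, "peripheral"),
        ],
    )
    def test_hierarchy(self, rank, eig, betw, deg, expected):
        import pandas as pd
        table = pd.DataFrame({"rank": [rank], "eigenvector": [eig],
                              "betweenness": [betw], "degree": [deg]})
        assert classify_roles(table).iloc[0] == expected


def test_empty_graph_is_error():
    with pytest.raises(DataError):
        centralities(nx.Graph())


def test_centrality_weights_mapping():
    t = centralities(star())
    w = centrality_weights(t)
    assert set(w) == {"hub", "leaf0", "leaf1", "leaf2", "leaf3"}
    assert w["hub"] == pytest.approx(t.at["hub", "integrated"])
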
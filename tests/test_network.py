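import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dcmnet.diffcorr import DiffCorrResult
from dcmnet.network import (
    build_network,
    centralities,
    export_network,
    hub_list,
    identify_hubs,
    mean_degree,
    node_table,
    read_graphml,
)


def result_from_pairs(pairs, alpha=0.05):
    """DiffCorrResult whose 'significant' pairs are exactly `pairs`.

    pairs: list of (i, j, r_diff, p_perm).
    """
    rows = [
        {"metabolite_i": i, "metabolite_j": j, "r_plasma": 0.0, "r_jf": 0.0,
         "z_plasma": 0.0, "z_jf": 0.0, "r_diff": rd, "p_perm": p}
        for i, j, rd, p in pairs
    ]
    table = pd.DataFrame(
        rows, columns=["metabolite_i", "metabolite_j", "r_plasma", "r_jf",
                       "z_plasma", "z_jf", "r_diff", "p_perm"]
    )
    table["sig_nominal"] = table["p_perm"] < alpha if len(table) else []
    return DiffCorrResult(table=table, n_plasma=50, n_jf=50, alpha=alpha)


# ---------------------------------------------------------------- oracles

def bfs_distances(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_shortest_paths(adj, s, t, dist_st):
    """Enumerate every shortest s-t path by depth-first search."""
    paths = []

    def walk(u, path):
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if v not in path and len(path) <= dist_st:
                dist_vt = bfs_distances(adj, v).get(t)
                if dist_vt is not None and len(path) + dist_vt == dist_st:
                    path.append(v)
                    walk(v, path)
                    path.pop()

    walk(s, [s])
    return paths


def brute_centralities(G):
    """Degree, normalized betweenness and Wasserman-Faust closeness by
    exhaustive shortest-path enumeration (small graphs only)."""
    nodes = sorted(G.nodes)
    n = len(nodes)
    adj = {v: sorted(G.neighbors(v)) for v in nodes}
    degree = {v: len(adj[v]) for v in nodes}
    betw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_distances(adj, s).get(t)
        if dist is None:
            continue
        paths = all_shortest_paths(adj, s, t, dist)
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            betw[v] += frac
    norm = (n - 1) * (n - 2) / 2.0
    betw = {v: (b / norm if norm else 0.0) for v, b in betw.items()}
    clos = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        k = len(dist)  # component size including v
        total = sum(dist.values())
        if k <= 1 or total == 0:
            clos[v] = 0.0
        else:
            clos[v] = ((k - 1) / (n - 1)) * ((k - 1) / total)
    return degree, betw, clos


# ------------------------------------------------------------------ tests

class TestBuildNetwork:
    def test_star_topology(self):
        res = result_from_pairs(
            [("A", "B", 1.0, 0.001), ("A", "C", -2.0, 0.001),
             ("A", "D", 3.0, 0.001), ("B", "C", 0.5, 0.5)]
        )
        G = build_network(res, tier="nominal")
        assert G.number_of_nodes() == 4 and G.number_of_edges() == 3
        assert G.degree["A"] == 3
        assert G.edges["A", "C"]["sign"] == "negative"
        assert G.edges["A", "B"]["sign"] == "positive"

    def test_no_isolated_nodes(self):
        res = result_from_pairs([("A", "B", 1.0, 0.001), ("C", "D", 1.0, 0.9)])
        G = build_network(res, tier="nominal")
        assert set(G.nodes) == {"A", "B"}

    def test_empty_result_gives_empty_network(self):
        G = build_network(result_from_pairs([]), tier="nominal")
        assert G.number_of_nodes() == 0

    def test_mean_degree_identity(self):
        rng = np.random.default_rng(0)
        pairs = [(f"M{i}", f"M{j}", 1.0, 0.001)
                 for i, j in {tuple(sorted(rng.integers(0, 30, 2)))
                              for _ in range(60)} if i != j]
        G = build_network(result_from_pairs(pairs))
        assert mean_degree(G) == pytest.approx(
            2 * G.number_of_edges() / G.number_of_nodes()
        )

    def test_signs_partition_edges(self):
        rng = np.random.default_rng(1)
        pairs = [(f"M{k}", f"M{k+1}", rng.normal(), 0.001) for k in range(20)]
        G = build_network(result_from_pairs(pairs))
        pos = sum(d["sign"] == "positive" for _, _, d in G.edges(data=True))
        neg = sum(d["sign"] == "negative" for _, _, d in G.edges(data=True))
        assert pos + neg == G.number_of_edges()

    def test_adjusted_tier_requires_flags(self):
        with pytest.raises(ValueError, match="adjusted"):
            build_network(result_from_pairs([("A", "B", 1.0, 0.001)]),
                          tier="adjusted")


class TestCentralities:
    def test_path_graph(self):
        G = nx.path_graph(["A", "B", "C"])
        centralities(G)
        assert G.nodes["B"]["betweenness"] == pytest.approx(1.0)
        assert G.nodes["A"]["betweenness"] == 0.0
        assert G.nodes["C"]["betweenness"] == 0.0

    def test_triangle(self):
        G = nx.complete_graph(3)
        centralities(G)
        for v in G:
            assert G.nodes[v]["betweenness"] == 0.0
            assert G.nodes[v]["closeness"] == pytest.approx(1.0)
            assert G.nodes[v]["degree"] == 2

    def test_star(self):
        G = nx.star_graph(5)  # center 0, leaves 1..5
        centralities(G)
        assert G.nodes[0]["degree"] == 5
        assert all(G.nodes[v]["degree"] == 1 for v in range(1, 6))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            centralities(nx.Graph())

    def test_matches_exhaustive_enumeration_on_small_graphs(self):
        """Degree/betweenness/closeness equal brute-force path enumeration."""
        rng = np.random.default_rng(2024)
        for case in range(200):
            n = int(rng.integers(2, 8))
            G = nx.Graph()
            G.add_nodes_from(range(n))
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.4:
                    G.add_edge(i, j)
            centralities(G)
            deg, bet, clo = brute_centralities(G)
            for v in G:
                assert G.nodes[v]["degree"] == deg[v]
                assert G.nodes[v]["betweenness"] == pytest.approx(bet[v], abs=1e-9)
                assert G.nodes[v]["closeness"] == pytest.approx(clo[v], abs=1e-9)

    def test_removing_top_degree_node_never_increases_degrees(self):
        rng = np.random.default_rng(9)
        G = nx.gnp_random_graph(15, 0.3, seed=4)
        top = max(G.nodes, key=lambda v: G.degree[v])
        before = {v: G.degree[v] for v in G if v != top}
        H = G.copy()
        H.remove_node(top)
        assert all(H.degree[v] <= before[v] for v in H)


class TestHubs:
    def test_star_center_is_the_only_hub(self):
        G = nx.star_graph(10)
        identify_hubs(G, 0.9, 0.9)
        assert hub_list(G) == [0] or hub_list(G) == ["0"]
        assert sum(d["is_hub"] for _, d in G.nodes(data=True)) == 1

    def test_regular_ring_has_no_hubs_under_strict_ties(self):
        G = nx.cycle_graph(12)
        identify_hubs(G, 0.9, 0.9, ties="strict")
        assert hub_list(G) == []
        # with tie inclusion every node of the regular graph qualifies
        identify_hubs(G, 0.9, 0.9, ties="include")
        assert len(hub_list(G)) == 12

    def test_two_disjoint_stars_have_two_hubs(self):
        G = nx.Graph()
        for leaf in range(1, 7):
            G.add_edge("c1", f"a{leaf}")
            G.add_edge("c2", f"b{leaf}")
        identify_hubs(G, 0.9, 0.9)
        assert hub_list(G) == ["c1", "c2"]

    def test_and_combine_is_stricter_than_or(self):
        G = nx.barbell_graph(5, 2)
        or_hubs = set(hub_list(identify_hubs(G.copy(), 0.7, 0.7, combine="or")))
        and_hubs = set(hub_list(identify_hubs(G.copy(), 0.7, 0.7, combine="and")))
        assert and_hubs <= or_hubs

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            identify_hubs(nx.Graph())


class TestExport:
    def star(self):
        res = result_from_pairs(
            [("A", "B", 1.0, 0.001), ("A", "C", -1.0, 0.001),
             ("A", "D", 2.0, 0.001)]
        )
        G = build_network(res)
        centralities(G)
        identify_hubs(G)
        return G

    def test_sif_three_lines_with_sign_types(self, tmp_path):
        p = export_network(self.star(), tmp_path / "net.sif", "sif")
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 3
        assert any("neg_dc" in ln for ln in lines)
        assert (tmp_path / "net.nodes.tsv").exists()

    def test_graphml_round_trip(self, tmp_path):
        G = self.star()
        p = export_network(G, tmp_path / "net.graphml", "graphml")
        H = read_graphml(p)
        assert set(H.nodes) == set(G.nodes)
        assert {frozenset(e) for e in H.edges} == {frozenset(e) for e in G.edges}
        for v in G:
            for attr in ("degree", "betweenness", "closeness", "is_hub"):
                assert H.nodes[v][attr] == pytest.approx(G.nodes[v][attr])
        for u, v, d in G.edges(data=True):
            assert H.edges[u, v]["sign"] == d["sign"]
            assert H.edges[u, v]["r_diff"] == pytest.approx(d["r_diff"])

    def test_empty_network_exports_validly(self, tmp_path):
        G = nx.Graph()
        for fmt, name in (("graphml", "e.graphml"), ("sif", "e.sif"),
                          ("edge-table", "e.tsv")):
            p = export_network(G, tmp_path / name, fmt)
            assert p.exists()
        assert read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(nx.Graph(), tmp_path / "x", "gexf")

    def test_deterministic_bytes(self, tmp_path):
        G = self.star()
        p1 = export_network(G, tmp_path / "a.graphml", "graphml")
        p2 = export_network(G, tmp_path / "b.graphml", "graphml")
        assert p1.read_bytes() == p2.read_bytes()

    def test_node_table_sorted(self):
        t = node_table(self.star())
        assert t["metabolite"].tolist() == sorted(t["metabolite"])
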
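"""Weighted network topology: loading, components, the five centralities
and the weighted k-shell decomposition."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tispec.network import (
    WeightedNetwork,
    build_network,
    centralities,
    diameter_unweighted,
    group_topology_compare,
    largest_component,
    load_edges,
    weighted_kshell,
)


def write_edges(path, rows):
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]) \
        .to_csv(path, sep="\t", index=False)


def enumerate_betweenness(g: nx.Graph) -> dict:
    """Exhaustive oracle: enumerate all simple paths per unordered pair,
    keep the minimum-total-w_sp ones, split one unit of credit equally."""
    btw = {n: 0.0 for n in g.nodes}
    for s, t in combinations(g.nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        lengths = [
            sum(g[u][v]["w_sp"] for u, v in zip(p, p[1:])) for p in paths
        ]
        best = min(lengths)
        shortest = [p for p, ln in zip(paths, lengths) if ln <= best + 1e-12]
        for p in shortest:
            for inner in p[1:-1]:
                btw[inner] += 1.0 / len(shortest)
    return btw


class TestLoadEdges:
    def test_bidirectional_duplicates_collapse(self, tmp_path):
        write_edges(tmp_path / "e.tsv", [("A", "B", 700), ("B", "A", 700)])
        net = load_edges(tmp_path / "e.tsv")
        assert net.n_edges == 1
        assert net.graph["A"]["B"]["score"] == pytest.approx(0.7)
        assert net.graph["A"]["B"]["w_sp"] == pytest.approx(0.3)

    def test_self_loop_dropped_with_warning(self, tmp_path):
        write_edges(tmp_path / "e.tsv", [("A", "A", 900), ("A", "B", 500)])
        with pytest.warns(UserWarning, match="self-loop"):
            net = load_edges(tmp_path / "e.tsv")
        assert net.n_edges == 1

    def test_score_out_of_range_rejected_with_line(self, tmp_path):
        write_edges(tmp_path / "e.tsv", [("A", "B", 1700)])
        with pytest.raises(ValueError, match="line 2"):
            load_edges(tmp_path / "e.tsv")

    def test_min_score_filter(self, tmp_path):
        write_edges(tmp_path / "e.tsv", [("A", "B", 300), ("B", "C", 800)])
        assert load_edges(tmp_path / "e.tsv", min_score=400).n_edges == 1

    def test_edge_count_matches_frozenset_oracle(self, tmp_path):
        rng = np.random.default_rng(9)
        rows = [
            (f"N{rng.integers(0, 40)}", f"N{rng.integers(0, 40)}",
             int(rng.integers(150, 1000)))
            for _ in range(1000)
        ]
        write_edges(tmp_path / "e.tsv", rows)
        net = load_edges(tmp_path / "e.tsv")
        oracle = {frozenset((u, v)) for u, v, _ in rows if u != v}
        assert net.n_edges == len(oracle)


class TestComponents:
    def test_two_triangles_and_edge_pick_first_triangle(self):
        edges = [("A", "B", 0.9), ("B", "C", 0.9), ("C", "A", 0.9),
                 ("X", "Y", 0.9), ("Y", "Z", 0.9), ("Z", "X", 0.9),
                 ("P", "Q", 0.9)]
        lcc = largest_component(build_network(edges))
        assert set(lcc.graph.nodes) == {"A", "B", "C"}

    def test_connected_graph_is_identity(self):
        net = build_network([("A", "B", 0.5), ("B", "C", 0.5)])
        lcc = largest_component(net)
        assert set(lcc.graph.nodes) == set(net.graph.nodes)

    def test_size_matches_bfs_flood_fill(self):
        rng = np.random.default_rng(1)
        edges = [
            (f"N{rng.integers(0, 200)}", f"N{rng.integers(0, 200)}", 0.5)
            for _ in range(180)
        ]
        edges = [(u, v, s) for u, v, s in edges if u != v]
        net = build_network(edges)
        # hand BFS flood fill
        adj = {}
        for u, v, _ in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        seen, best = set(), 0
        for start in adj:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                n = stack.pop()
                if n in comp:
                    continue
                comp.add(n)
                stack.extend(adj[n] - comp)
            seen |= comp
            best = max(best, len(comp))
        assert largest_component(net).n_nodes == best


class TestDiameter:
    def test_path_of_four(self):
        net = build_network([("A", "B", 0.9), ("B", "C", 0.9), ("C", "D", 0.9)])
        assert diameter_unweighted(net) == 3

    def test_complete_graph(self):
        edges = [(a, b, 0.9) for a, b in combinations("ABCDE", 2)]
        assert diameter_unweighted(build_network(edges)) == 1

    def test_disconnected_rejected(self):
        net = build_network([("A", "B", 0.9), ("X", "Y", 0.9)])
        with pytest.raises(ValueError):
            diameter_unweighted(net)


class TestCentralities:
    def test_path_betweenness_and_closeness(self):
        net = build_network([("A", "B", 0.999), ("B", "C", 0.999)])
        tab = centralities(net)
        assert tab.loc["B", "betweenness"] == pytest.approx(1.0)
        assert tab.loc["A", "betweenness"] == 0.0
        # distances are 0.001 per hop; closeness = (n-1)/sum(d)
        assert tab.loc["B", "closeness"] == pytest.approx(2 / 0.002)

    def test_star_center_covers_all_leaf_pairs(self):
        net = build_network([("C", x, 0.999) for x in "XYZ"])
        tab = centralities(net)
        assert tab.loc["C", "betweenness"] == pytest.approx(3.0)

    def test_triangle_detour_through_strong_edges(self):
        """A-C direct (s=0.5, length 0.5) loses to A-B-C (0.1+0.1)."""
        net = build_network([("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.5)])
        tab = centralities(net)
        oracle = enumerate_betweenness(net.graph)
        for n in "ABC":
            assert tab.loc[n, "betweenness"] == pytest.approx(oracle[n])
        assert tab.loc["B", "betweenness"] == pytest.approx(1.0)

    def test_strength_is_incident_score_sum(self):
        net = build_network([("A", "B", 0.4), ("B", "C", 0.6)])
        tab = centralities(net)
        assert tab.loc["B", "strength"] == pytest.approx(1.0)

    def test_eigenvector_matches_networkx_reference(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(12, 0.4, seed=5)
        net = WeightedNetwork(nx.Graph())
        for u, v in g.edges:
            s = float(rng.uniform(0.2, 0.99))
            net.graph.add_edge(u, v, score=s, w_sp=1 - s)
        net = largest_component(net)
        tab = centralities(net)
        ref = nx.eigenvector_centrality_numpy(net.graph, weight="score")
        ref_vec = np.array([ref[n] for n in tab.index])
        ref_vec = np.abs(ref_vec) / np.linalg.norm(ref_vec)
        assert np.allclose(tab["eigenvector"], ref_vec, atol=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_betweenness_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 2**31)))
        if not nx.is_connected(g):
            return
        net = WeightedNetwork(nx.Graph())
        for u, v in g.edges:
            s = float(rng.uniform(0.1, 0.99))
            net.graph.add_edge(u, v, score=s, w_sp=1 - s)
        tab = centralities(net)
        oracle = enumerate_betweenness(net.graph)
        for node in net.graph.nodes:
            assert tab.loc[node, "betweenness"] == pytest.approx(
                oracle[node], abs=1e-9
            )


class TestWeightedKShell:
    def test_triangle_unit_scores_all_shell_two(self):
        net = build_network([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)])
        assert weighted_kshell(net) == {"A": 2, "B": 2, "C": 2}

    def test_path_cascades_within_level(self):
        net = build_network([("A", "B", 1.0), ("B", "C", 1.0)])
        assert weighted_kshell(net) == {"A": 1, "B": 1, "C": 1}

    def test_two_clique_fixture_matches_hand_trace(self):
        """Strong 4-clique (s=0.9) hangs off a weak 4-clique (s=0.3) via
        one s=0.3 edge; the hand pruning trace follows the docstring's
        rule: k' = round(sqrt(degree * strength)).

        Weak clique: k'=round(sqrt(3*0.9))=2 internally; bridge node has
        k'=round(sqrt(4*1.2))=2.  Strong clique: round(sqrt(3*2.7))=3;
        its bridge end round(sqrt(4*3.0))=3.  Level 2 removes the whole
        weak clique (cascade), level 3 the strong one.
        """
        weak = [(u, v, 0.3) for u, v in combinations("abcd", 2)]
        strong = [(u, v, 0.9) for u, v in combinations("efgh", 2)]
        bridge = [("d", "e", 0.3)]
        shells = weighted_kshell(build_network(weak + strong + bridge))
        assert {n: shells[n] for n in "abcd"} == dict.fromkeys("abcd", 2)
        assert {n: shells[n] for n in "efgh"} == dict.fromkeys("efgh", 3)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_unit_scores_reduce_to_classic_k_core(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(0, 2**31)))
        net = WeightedNetwork(nx.Graph())
        net.graph.add_nodes_from(g.nodes)
        for u, v in g.edges:
            net.graph.add_edge(u, v, score=1.0, w_sp=0.0)
        shells = weighted_kshell(net)
        core = nx.core_number(g)
        assert shells == core


class TestScalingInvariants:
    def test_removing_edge_never_increases_strength(self):
        net = build_network([("A", "B", 0.4), ("B", "C", 0.6), ("A", "C", 0.5)])
        before = dict(net.graph.degree(weight="score"))
        net.graph.remove_edge("A", "B")
        after = dict(net.graph.degree(weight="score"))
        assert all(after[n] <= before[n] + 1e-12 for n in after)

    def test_score_scaling_preserves_path_structure(self):
        edges = [("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.5)]
        c = 0.9  # 1 - c*s preserves the order of path lengths here
        base = centralities(build_network(edges))
        scaled = centralities(
            build_network([(u, v, c * s) for u, v, s in edges])
        )
        assert np.allclose(scaled["strength"], c * base["strength"])
        assert np.allclose(scaled["betweenness"], base["betweenness"])


class TestGroupCompare:
    def test_reference_group_has_no_p(self):
        net = build_network(
            [(f"N{i}", f"N{i + 1}", 0.9) for i in range(10)]
        )
        tab = centralities(net)
        groups = {"all": set(tab.index), "sub": set(list(tab.index)[:4])}
        out = group_topology_compare(tab, groups, "betweenness",
                                     reference="all")
        ref_row = out[out["group"] == "all"].iloc[0]
        assert np.isnan(ref_row["p"])

    def test_unmapped_group_gives_na_row(self):
        net = build_network([("A", "B", 0.9), ("B", "C", 0.9)])
        tab = centralities(net)
        out = group_topology_compare(
            tab, {"all": {"A", "B", "C"}, "ghost": {"Z"}},
            "betweenness", reference="all",
        )
        row = out[out["group"] == "ghost"].iloc[0]
        assert row["n"] == 0 and np.isnan(row["median"])

    def test_id_mapping_applied(self):
        net = build_network([("p1", "p2", 0.9), ("p2", "p3", 0.9)])
        tab = centralities(net)
        out = group_topology_compare(
            tab, {"ref": {"gA", "gB", "gC"}, "mid": {"gB"}},
            "betweenness", reference="ref",
            id_map={"p1": "gA", "p2": "gB", "p3": "gC"},
        )
        mid = out[out["group"] == "mid"].iloc[0]
        assert mid["n"] == 1
        assert mid["median"] == pytest.approx(1.0)
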
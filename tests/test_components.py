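"""Edge-removal sweep, final component structure, diameters, selection."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from dpcnet.components import (
    diameter_of,
    final_structure,
    select_major,
    sweep,
    vanishing_distribution,
    vanishing_point_of,
)
from dpcnet.network import dpcn_from_edges
from dpcnet.synthetic import PlantedGraphSpec, make_planted_graph, random_dpcn


class UnionFind:
    """Independent component counter (the sweep itself uses BFS)."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_count(edges):
    """Component count of the graph spanned by an edge list (isolated nodes
    cannot occur: every node comes from an edge)."""
    nodes = {u for e in edges for u in e[:2]}
    uf = UnionFind(nodes)
    for u, v, *_ in edges:
        uf.union(u, v)
    return len({uf.find(n) for n in nodes})


class TestSweep:
    def test_hand_traced_path(self):
        """Path a-b (w=1), b-c (w=2): prune a, then the graph empties."""
        trace = sweep(dpcn_from_edges([("a", "b", 1.0), ("b", "c", 2.0)]))
        assert trace.initial_count == 1
        assert [s.n_components for s in trace.steps] == [1, 0]
        assert [s.removed_magnitude for s in trace.steps] == [1.0, 2.0]
        assert trace.steps[0].smallest_remaining_magnitude == 2.0
        assert math.isnan(trace.steps[1].smallest_remaining_magnitude)

    def test_bridge_removal_splits(self):
        """Removing the last edge connecting two 2-edge clusters adds one
        component."""
        edges = [
            ("a", "b", 5.0), ("b", "c", 6.0),
            ("x", "y", 7.0), ("y", "z", 8.0),
            ("c", "x", 1.0),  # bridge, removed first
        ]
        trace = sweep(dpcn_from_edges(edges))
        assert trace.initial_count == 1
        assert trace.steps[0].n_components == 2

    def test_empty_graph_rejected(self):
        import networkx

        from dpcnet.network import DPCNGraph

        with pytest.raises(ValueError, match="empty"):
            sweep(DPCNGraph(networkx.Graph()))

    @pytest.mark.parametrize("seed", range(10))
    def test_union_find_oracle(self, seed):
        """At every step the BFS count matches union-find on the surviving
        edge set."""
        g = random_dpcn(n_nodes=40, n_edges=120, seed=seed)
        trace = sweep(g)
        order = sorted(
            (d["magnitude"], tuple(sorted((u, v))))
            for u, v, d in g.graph.edges(data=True)
        )
        for i, step in enumerate(trace.steps):
            surviving = [(u, v) for _, (u, v) in order[i + 1:]]
            assert step.n_components == union_find_count(surviving)

    def test_removed_magnitudes_non_decreasing(self):
        trace = sweep(random_dpcn(n_nodes=20, n_edges=60, seed=1))
        mags = [s.removed_magnitude for s in trace.steps]
        assert mags == sorted(mags)
        assert trace.steps[-1].n_components == 0

    def test_threshold_consistency(self):
        """The graph surviving all removals below w equals the direct
        magnitude >= w thresholding, at every unique magnitude w."""
        g = random_dpcn(n_nodes=25, n_edges=80, seed=2)
        order = sorted(
            (d["magnitude"], tuple(sorted((u, v))))
            for u, v, d in g.graph.edges(data=True)
        )
        for w in sorted({m for m, _ in order}):
            replay = {e for m, e in order if m >= w}
            direct = {
                tuple(sorted((u, v)))
                for u, v, d in g.graph.edges(data=True)
                if d["magnitude"] >= w
            }
            assert replay == direct


def connected_graphs_up_to(n_max):
    """All connected labelled graphs with 2..n_max nodes and >= 1 edge."""
    for n in range(2, n_max + 1):
        all_edges = list(itertools.combinations(range(n), 2))
        for r in range(n - 1, len(all_edges) + 1):
            for subset in itertools.combinations(all_edges, r):
                g = nx.Graph(subset)
                if g.number_of_nodes() == n and nx.is_connected(g):
                    yield subset


class TestRemovalTrichotomy:
    def test_exhaustive_small_graphs(self):
        """Each single removal changes the count by exactly +1 (bridge
        between two surviving parts), 0 (cycle edge, or a pruned endpoint)
        or -1 (a component's last edge) — checked against an independent
        classification on every connected graph with at most 5 nodes."""
        n_checked = 0
        for edge_set in connected_graphs_up_to(5):
            edges = [
                (f"n{u}", f"n{v}", float(i + 1))
                for i, (u, v) in enumerate(edge_set)
            ]
            g = dpcn_from_edges(edges)
            trace = sweep(g)
            counts = [trace.initial_count] + [s.n_components for s in trace.steps]
            surviving = {(u, v) for u, v, _ in edges}
            for step, (before, after) in zip(trace.steps, itertools.pairwise(counts)):
                delta = after - before
                assert delta in (-1, 0, 1)
                # independent classification of the removed edge
                u, v = step.removed_edge
                h = nx.Graph(list(surviving))
                h.remove_edge(u, v)
                du, dv = h.degree(u), h.degree(v)
                if du == 0 and dv == 0:
                    expected = -1  # last edge of its component
                elif du == 0 or dv == 0:
                    expected = 0  # dangling endpoint pruned away
                else:
                    expected = 1 if not nx.has_path(h, u, v) else 0
                assert delta == expected
                surviving = {
                    e for e in surviving if set(e) != {u, v}
                }
                n_checked += 1
        assert n_checked > 1000  # the enumeration really was exhaustive


class TestFinalStructure:
    def test_single_edge(self):
        g = dpcn_from_edges([("a", "b", 2.0)])
        final = final_structure(sweep(g), g)
        assert final.max_count == 1
        assert final.critical_weight == 2.0
        assert final.components[0].order == 2

    def test_two_disjoint_edges(self):
        """Max count 2 holds before any removal; the structure is taken at
        the pre-removal state (level of the smallest magnitude)."""
        g = dpcn_from_edges([("a", "b", 1.0), ("c", "d", 2.0)])
        final = final_structure(sweep(g), g)
        assert final.max_count == 2
        assert final.critical_weight == 1.0
        assert {c.nodes for c in final.components} == {
            frozenset(("a", "b")),
            frozenset(("c", "d")),
        }

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_recovery(self, seed):
        spec = PlantedGraphSpec(
            clusters=[(5, "path"), (4, "star"), (6, "cycle"), (2, "path"), (7, "random")],
            internal_range=(5.0, 8.0),
            bridge_range=(0.5, 2.0),
            seed=seed,
        )
        g, truth = make_planted_graph(spec)
        final = final_structure(sweep(g), g)
        assert final.max_count == truth["n_clusters"]
        assert {c.nodes for c in final.components} == {
            c["nodes"] for c in truth["clusters"]
        }

    def test_monotone_tail(self):
        """Past the critical weight no trace step exceeds the maximum."""
        for seed in range(5):
            g = random_dpcn(n_nodes=30, n_edges=90, seed=seed)
            trace = sweep(g)
            final = final_structure(trace, g)
            tail = [
                s.n_components
                for s in trace.steps
                if s.removed_magnitude >= final.critical_weight
            ]
            assert all(c <= final.max_count for c in tail)

    def test_max_count_matches_component_list(self):
        g = random_dpcn(n_nodes=30, n_edges=60, seed=7)
        final = final_structure(sweep(g), g)
        assert final.max_count == len(final.components)
        for c in final.components:
            assert c.size >= c.order - 1
            assert c.order >= 2 and c.diameter >= 1


class TestDiameter:
    def test_small_shapes(self):
        assert diameter_of(nx.Graph([("a", "b")])) == 1
        assert diameter_of(nx.path_graph(3)) == 2
        assert diameter_of(nx.cycle_graph(3)) == 1

    def test_floyd_warshall_oracle(self):
        """Hop diameter equals the max finite entry of the all-pairs
        shortest-path matrix computed by Floyd-Warshall."""
        from scipy.sparse.csgraph import floyd_warshall

        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(5, 30))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0 or not nx.is_connected(g):
                g = nx.connected_watts_strogatz_graph(
                    n, 4, 0.3, seed=int(rng.integers(1 << 30))
                )
            adj = nx.to_scipy_sparse_array(g, format="csr")
            dist = floyd_warshall(adj, unweighted=True, directed=False)
            assert diameter_of(g) == int(dist.max())

    def test_disconnected_rejected(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="connected"):
            diameter_of(g)


class TestVanishingPoint:
    def test_max_magnitude(self):
        g = nx.Graph()
        g.add_edge("a", "b", magnitude=1.0)
        g.add_edge("b", "c", magnitude=4.45)
        assert vanishing_point_of(g) == 4.45
        single = nx.Graph()
        single.add_edge("a", "b", magnitude=2.0)
        assert vanishing_point_of(single) == 2.0

    @pytest.mark.parametrize("seed", range(5))
    def test_disappearance_step_matches(self, seed):
        """Running the sweep to exhaustion, the step at which a final
        component's node set fully disappears removes an edge whose
        magnitude equals the recorded vanishing point."""
        spec = PlantedGraphSpec(
            clusters=[(4, "path"), (3, "star"), (5, "cycle"), (2, "path")],
            seed=seed,
        )
        g, _ = make_planted_graph(spec)
        trace = sweep(g)
        final = final_structure(trace, g)
        # replay the sweep tracking which nodes remain
        alive = set(g.graph.nodes)
        order = sorted(
            (d["magnitude"], tuple(sorted((u, v))))
            for u, v, d in g.graph.edges(data=True)
        )
        surviving = nx.Graph([(u, v) for _, (u, v) in order])
        death_magnitude = {}
        for mag, (u, v) in order:
            surviving.remove_edge(u, v)
            for node in (u, v):
                if surviving.degree(node) == 0:
                    surviving.remove_node(node)
                    alive.discard(node)
                    death_magnitude[node] = mag
        for comp in final.components:
            assert max(death_magnitude[n] for n in comp.nodes) == pytest.approx(
                comp.vanishing_point
            )


class TestSelection:
    def test_all_dyads_selects_nothing(self):
        g = dpcn_from_edges([("a", "b", 1.0), ("c", "d", 2.0), ("e", "f", 3.0)])
        final = final_structure(sweep(g), g)
        assert select_major(final) == []

    def test_path_among_dyads(self):
        edges = [("p1", "p2", 5.0), ("p2", "p3", 5.0), ("p3", "p4", 5.0)]
        edges += [(f"x{i}", f"y{i}", 4.0 + 0.1 * i) for i in range(3)]
        g = dpcn_from_edges(edges)
        final = final_structure(sweep(g), g)
        major = select_major(final, d_min=3)
        assert len(major) == 1 and major[0].diameter == 3
        assert major[0].nodes == frozenset(("p1", "p2", "p3", "p4"))

    def test_planted_pathway_selected(self, planted_spec):
        g, truth = make_planted_graph(planted_spec)
        final = final_structure(sweep(g), g)
        major = select_major(final, d_min=3)
        expected = {
            c["nodes"]
            for c in truth["clusters"]
            if c["analytic_diameter"] is not None and c["analytic_diameter"] >= 3
        }
        got = {c.nodes for c in major}
        assert expected <= got
        # anything extra must be a random-topology cluster that really has d >= 3
        for extra in got - expected:
            assert next(
                c["topology"] for c in truth["clusters"] if c["nodes"] == extra
            ) == "random"
        vps = [c.vanishing_point for c in major]
        assert vps == sorted(vps, reverse=True)

    def test_monotone_in_d_min(self):
        g = random_dpcn(n_nodes=40, n_edges=70, seed=3)
        final = final_structure(sweep(g), g)
        sizes = [len(select_major(final, d_min=d)) for d in range(1, 7)]
        assert sizes[0] == len(final.components)
        assert all(a >= b for a, b in itertools.pairwise(sizes))


class TestVanishingDistribution:
    def test_single_component(self):
        g = dpcn_from_edges([("a", "b", 3.0)])
        final = final_structure(sweep(g), g)
        assert vanishing_distribution(final)["median"] == 3.0

    def test_median_of_three(self):
        g = dpcn_from_edges([("a", "b", 1.0), ("c", "d", 2.0), ("e", "f", 3.0)])
        final = final_structure(sweep(g), g)
        dist = vanishing_distribution(final)
        assert dist["median"] == 2.0 and dist["n_components"] == 3

    def test_sorted_middle_oracle(self):
        rng = np.random.default_rng(12)
        mags = rng.uniform(3.0, 9.0, size=36)
        g = dpcn_from_edges(
            [(f"u{i}", f"v{i}", m) for i, m in enumerate(mags)]
        )
        final = final_structure(sweep(g), g)
        dist = vanishing_distribution(final)
        s = np.sort(mags)
        assert dist["median"] == pytest.approx((s[17] + s[18]) / 2)
        assert len(dist["table"]) == 36
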
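from __future__ import annotations

from fractions import Fraction

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivinet.centrality import (
    ScoreConfig,
    all_centralities,
    betweenness,
    clusterrank,
    collective_influence,
    degree_centrality,
    h_index,
    local_h_index,
    neighborhood_connectivity,
)
from ivinet.graph import Network

from conftest import complete_graph, cycle_graph, path_graph


def to_nx(net: Network) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    return g


def brute_betweenness(net: Network) -> dict[str, Fraction]:
    """Independent oracle: exhaustive simple-path enumeration per pair."""
    g = to_nx(net)
    bc = {v: Fraction(0) for v in net.nodes}
    nodes = net.nodes
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if not nx.has_path(g, s, t):
                continue
            d = nx.shortest_path_length(g, s, t)
            geodesics = [p for p in nx.all_simple_paths(g, s, t, cutoff=d) if len(p) == d + 1]
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in geodesics if v in p)
                if through:
                    bc[v] += Fraction(through, len(geodesics))
    return bc


# -- trivial worked examples -------------------------------------------------


class TestDegree:
    def test_path(self, p3):
        dc = degree_centrality(p3)
        assert dc == {"A": 1, "B": 2, "C": 1}

    def test_k5(self, k5):
        assert set(degree_centrality(k5).values()) == {4}

    def test_isolated(self):
        assert degree_centrality(Network(nodes=["X"]))["X"] == 0


class TestBetweenness:
    def test_path_interior(self, p3):
        bc = betweenness(p3)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_c4_each_half(self):
        bc = betweenness(cycle_graph("ABCD"))
        assert all(v == pytest.approx(0.5) for v in bc.values())

    def test_k5_all_zero(self, k5):
        assert all(v == 0.0 for v in betweenness(k5).values())

    def test_disconnected_pairs_contribute_zero(self):
        net = Network(edges=[("A", "B"), ("B", "C")], nodes=["D"])
        bc = betweenness(net)
        assert bc["D"] == 0.0 and bc["B"] == 1.0

    def test_exact_mode_matches_oracle(self):
        net = Network(edges=[("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C"), ("D", "E")])
        assert betweenness(net, exact=True) == brute_betweenness(net)


class TestNeighborhoodConnectivity:
    def test_star(self, star5):
        nc = neighborhood_connectivity(star5)
        assert nc["Z"] == 1.0
        assert nc["A"] == 5.0

    def test_path(self, p3):
        nc = neighborhood_connectivity(p3)
        assert nc["A"] == 2.0 and nc["B"] == 1.0

    def test_regular_graph_constant(self):
        net = cycle_graph("ABCDEF")
        assert set(neighborhood_connectivity(net).values()) == {2.0}

    def test_isolated_zero(self):
        assert neighborhood_connectivity(Network(nodes=["X"]))["X"] == 0.0


class TestHIndex:
    def test_k4(self):
        assert set(h_index(complete_graph("ABCD")).values()) == {3}

    def test_star_center(self, star5):
        assert h_index(star5)["Z"] == 1

    def test_mixed_neighbor_degrees(self):
        # center X with neighbor degrees {3, 3, 2, 1}: h=3 fails, h=2 holds
        net = Network(
            edges=[
                ("X", "A"), ("X", "B"), ("X", "C"), ("X", "D"),
                ("A", "B"), ("A", "E"), ("B", "F"), ("C", "A"),
            ]
        )
        deg = degree_centrality(net)
        assert sorted(deg[n] for n in net.neighbors("X")) == [1, 2, 3, 4]
        assert h_index(net)["X"] == 2

    def test_h_bounded_by_degree(self):
        net = Network(edges=[("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        h, dc = h_index(net), degree_centrality(net)
        assert all(h[v] <= dc[v] for v in net.nodes)


class TestLocalHIndex:
    def test_p3(self, p3):
        lh = local_h_index(p3)
        assert lh == {"A": 2, "B": 3, "C": 2}

    def test_k4(self):
        assert set(local_h_index(complete_graph("ABCD")).values()) == {12}

    def test_isolated_zero(self):
        assert local_h_index(Network(nodes=["X"]))["X"] == 0

    def test_second_order_variant(self, p3):
        cfg = ScoreConfig(lh_second_order=True)
        lh = local_h_index(p3, cfg)
        # A's second-order neighborhood is {B, C}: degrees (2, 1) -> h = 1
        assert lh["A"] == 1


class TestClusterRank:
    def test_triangle(self, triangle):
        cr = clusterrank(triangle)
        assert all(v == pytest.approx(0.6) for v in cr.values())

    def test_star_center(self, star5):
        assert clusterrank(star5)["Z"] == pytest.approx(10.0)

    def test_low_degree_no_penalty(self, p3):
        cr = clusterrank(p3)
        assert cr["A"] == pytest.approx(3.0)  # f=1, neighbor B has degree 2

    def test_configurable_base(self, triangle):
        cr = clusterrank(triangle, ScoreConfig(clusterrank_base=100.0))
        assert all(v == pytest.approx(0.06) for v in cr.values())


class TestCollectiveInfluence:
    def test_k3_d1(self, triangle):
        ci = collective_influence(triangle, ScoreConfig(ci_radius=1))
        assert all(v == 2.0 for v in ci.values())

    def test_star_d1_zero(self, star5):
        ci = collective_influence(star5, ScoreConfig(ci_radius=1))
        assert all(v == 0.0 for v in ci.values())

    def test_p4_interior_d1(self):
        ci = collective_influence(path_graph("ABCD"), ScoreConfig(ci_radius=1))
        assert ci["B"] == 1.0

    def test_beyond_diameter_zero(self):
        net = path_graph("ABC")  # diameter 2
        ci = collective_influence(net, ScoreConfig(ci_radius=5))
        assert all(v == 0.0 for v in ci.values())

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            ScoreConfig(ci_radius=0)


class TestAllCentralities:
    def test_consistent_with_per_op(self, p3):
        cfg = ScoreConfig()
        table = all_centralities(p3, cfg)
        assert table.dc == degree_centrality(p3)
        assert table.bc == betweenness(p3)
        assert table.nc == neighborhood_connectivity(p3)
        assert table.h == h_index(p3)
        assert table.lh == local_h_index(p3, cfg)
        assert table.cr == clusterrank(p3, cfg)
        assert table.ci == collective_influence(p3, cfg)

    def test_edgeless_graph(self):
        net = Network(nodes=["A", "B"])
        table = all_centralities(net)
        assert all(table.column(c) == {"A": 0, "B": 0} for c in ("dc", "bc", "nc", "h", "lh", "cr", "ci"))

    def test_unknown_column(self, p3):
        with pytest.raises(KeyError):
            all_centralities(p3).column("pagerank")


# -- property tests ----------------------------------------------------------

edge_lists = st.lists(
    st.tuples(st.integers(0, 9), st.integers(0, 9))
    .filter(lambda t: t[0] != t[1])
    .map(lambda t: (f"N{t[0]}", f"N{t[1]}")),
    min_size=1,
    max_size=25,
)


@given(edges=edge_lists)
@settings(max_examples=60, deadline=None)
def test_h_le_dc_and_lh_ge_h(edges):
    net = Network(edges=edges)
    dc, h, lh = degree_centrality(net), h_index(net), local_h_index(net)
    for v in net.nodes:
        assert h[v] <= dc[v]
        assert lh[v] >= h[v]


@given(edges=edge_lists, data=st.data())
@settings(max_examples=40, deadline=None)
def test_label_invariance(edges, data):
    net = Network(edges=edges)
    perm = data.draw(st.permutations(net.nodes))
    # relabel according to a random permutation of the target labels
    mapping = dict(zip(perm, [f"P{i}" for i in range(len(perm))]))
    relabeled = Network(
        nodes=[mapping[n] for n in net.nodes],
        edges=[(mapping[u], mapping[v]) for u, v in net.edges],
    )
    t1 = all_centralities(net)
    t2 = all_centralities(relabeled)
    for col in ("dc", "bc", "nc", "h", "lh", "cr", "ci"):
        c1, c2 = t1.column(col), t2.column(col)
        for v in net.nodes:
            assert c2[mapping[v]] == pytest.approx(c1[v])


@pytest.mark.parametrize(
    "net",
    [cycle_graph("ABCDE"), complete_graph("ABCDEF"), cycle_graph("ABCDEFGH")],
    ids=["C5", "K6", "C8"],
)
def test_vertex_transitive_constant(net):
    table = all_centralities(net)
    for col in ("dc", "bc", "nc", "h", "lh", "cr", "ci"):
        assert len(set(table.column(col).values())) == 1


@pytest.mark.parametrize("seed", range(5))
def test_betweenness_matches_networkx_random(seed):
    g = nx.gnm_random_graph(80, 200, seed=seed)
    net = Network(nodes=[f"N{v}" for v in g], edges=[(f"N{u}", f"N{v}") for u, v in g.edges()])
    ref = nx.betweenness_centrality(g, normalized=False)
    mine = betweenness(net)
    for v in g:
        assert mine[f"N{v}"] == pytest.approx(ref[v], abs=1e-9)


@pytest.mark.parametrize("seed", range(3))
def test_exact_betweenness_matches_brute_force_random(seed):
    g = nx.gnp_random_graph(7, 0.45, seed=seed)
    net = Network(nodes=[f"N{v}" for v in g], edges=[(f"N{u}", f"N{v}") for u, v in g.edges()])
    assert betweenness(net, exact=True) == brute_betweenness(net)
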
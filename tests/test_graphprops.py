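import math

import networkx as nx
import numpy as np
import pytest

from coexnet import (
    EdgeRecord,
    ValidationError,
    assortativity_nominal,
    average_path_length,
    diameter,
    key_nodes,
    louvain_lc_modularity,
    maximum_component,
    modularity,
    report,
    transitivity,
)
from coexnet.graphprops import maximum_component as maxcomp, metrics_table
from coexnet.nullmodel import NodeRecord, SignedNetwork, Thresholds

import oracles


def random_graph(seed, n_max=50):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.03, 0.25))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    return nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})


class TestClosedForms:
    def test_component_sizes(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        assert maximum_component(g).number_of_nodes() == 3
        h = nx.path_graph(5)
        assert set(maximum_component(h)) == set(h)

    def test_path_of_nine_diameter(self):
        assert diameter(nx.path_graph(9)) == 8

    def test_complete_graph_diameter_one(self):
        assert diameter(nx.complete_graph(5)) == 1

    def test_diameter_requires_connected(self):
        with pytest.raises(ValidationError, match="maximum_component"):
            diameter(nx.Graph([("a", "b"), ("x", "y")]))

    def test_average_path_length(self):
        assert average_path_length(nx.complete_graph(3)) == pytest.approx(1.0)
        assert average_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_transitivity_triangle_and_star(self):
        assert transitivity(nx.complete_graph(3)) == pytest.approx(1.0)
        assert transitivity(nx.star_graph(4)) == 0.0

    def test_two_disjoint_triangles_modularity_half(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        part = [set(range(3)), set(range(3, 6))]
        assert modularity(g, part) == pytest.approx(0.5)

    def test_single_community_modularity_zero(self):
        g = nx.complete_graph(4)
        assert modularity(g, [set(g.nodes)]) == pytest.approx(0.0)

    def test_louvain_two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part, q = louvain_lc_modularity(g, seed=1)
        assert sorted(map(sorted, part)) == [list(range(5)), list(range(5, 10))]
        assert q == pytest.approx(0.5)

    def test_louvain_complete_graph(self):
        part, q = louvain_lc_modularity(nx.complete_graph(6), seed=1)
        assert len(part) == 1 and q == pytest.approx(0.0)

    def test_louvain_beats_trivial_partition(self):
        g = random_graph(5)
        g = maximum_component(g)
        _, q = louvain_lc_modularity(g, seed=0)
        assert q >= modularity(g, [set(g.nodes)])

    def test_assortativity_pure_components(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        labels = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        assert assortativity_nominal(g, labels) == pytest.approx(1.0)

    def test_assortativity_bipartite(self):
        g = nx.complete_bipartite_graph(3, 4)
        labels = {n: ("L" if n < 3 else "R") for n in g.nodes}
        assert assortativity_nominal(g, labels) == pytest.approx(-1.0)

    def test_assortativity_single_label_nan(self):
        g = nx.path_graph(3)
        with pytest.warns(UserWarning):
            assert math.isnan(assortativity_nominal(g, {n: "X" for n in g}))

    def test_key_nodes_path_and_cycle(self):
        path = nx.path_graph(["a", "b", "c"])
        assert key_nodes(path) == ["b"]
        assert key_nodes(nx.cycle_graph(5)) == []


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(20))
    def test_metrics_match_bruteforce(self, seed):
        g = random_graph(seed)
        nodes, edges = list(g.nodes), list(g.edges)
        comps = oracles.components_floodfill(nodes, edges)
        assert maxcomp(g).number_of_nodes() == max(map(len, comps))
        mc = maximum_component(g)
        mn, me = list(mc.nodes), list(mc.edges)
        assert diameter(mc) == oracles.diameter_bfs(mn, me)
        if len(mn) > 1:
            assert average_path_length(mc) == pytest.approx(
                oracles.average_path_length_bfs(mn, me), abs=1e-9)
        assert transitivity(g) == pytest.approx(
            oracles.transitivity_triples(nodes, edges), abs=1e-9)
        rng = np.random.default_rng(seed)
        labels = {n: str(rng.integers(0, 3)) for n in nodes}
        part = {}
        for n, lab in labels.items():
            part.setdefault(lab, set()).add(n)
        if edges:
            assert modularity(g, list(part.values())) == pytest.approx(
                oracles.modularity_direct(nodes, edges, list(part.values())),
                abs=1e-9)
        if len(set(labels.values())) > 1 and edges:
            assert assortativity_nominal(g, labels) == pytest.approx(
                oracles.assortativity_mixing(nodes, edges, labels),
                abs=1e-9, nan_ok=True)
        aps = oracles.articulation_by_removal(nodes, edges)
        assert set(nx.articulation_points(g)) == aps
        bc = nx.betweenness_centrality(g, normalized=False)
        bco = oracles.betweenness_pairsum(nodes, edges)
        for n in nodes:
            assert bc[n] == pytest.approx(bco[n], abs=1e-9)
        assert set(key_nodes(g)) <= aps


def _net(edges):
    recs = [EdgeRecord(a, b, "pos" if w > 0 else "neg", w, 1.0)
            for a, b, w in edges]
    ids = sorted({e.node_a for e in recs} | {e.node_b for e in recs})
    deg = {i: sum(i in (e.node_a, e.node_b) for e in recs) for i in ids}
    return SignedNetwork([NodeRecord(i, "otu", degree=deg[i]) for i in ids],
                         recs, Thresholds(0.4, -0.4))


class TestReport:
    def test_positive_only_network_empty_exclusion_scope(self):
        net = _net([("a", "b", 0.5), ("b", "c", 0.6)])
        reps = {r.scope: r for r in report(net)}
        assert reps["co_exclusion"].n_nodes == 0
        assert reps["co_occurrence"].n_nodes == 3

    def test_single_edge_metrics(self):
        net = _net([("a", "b", 0.5)])
        rep = {r.scope: r for r in report(net)}["all"]
        assert rep.max_component_size == 2
        assert rep.diameter == 1
        assert rep.transitivity == 0.0

    def test_bipartite_exclusion_scope_transitivity_zero(self):
        # two-sided exclusion structure is bipartite, hence triangle-free
        edges = [(a, b, -0.5) for a in ("a1", "a2", "a3") for b in ("b1", "b2")]
        rep = {r.scope: r for r in report(_net(edges))}["co_exclusion"]
        assert rep.transitivity == 0.0

    def test_table_shape(self):
        net = _net([("a", "b", 0.5), ("b", "c", -0.4)])
        tab = metrics_table(report(net))
        assert list(tab.columns) == ["all", "co_occurrence", "co_exclusion"]
        assert tab.loc["n_edges", "all"] == 2
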
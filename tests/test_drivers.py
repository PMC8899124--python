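"""Driver identification: orientation, maximum matching, controllability,
node importance, rank-sum validation."""

import itertools
from math import comb

import networkx as nx
import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pandas as pd
import pytest
from scipy import stats

from dims.drivers import (
    DirectedInteractionNetwork,
    build_condition_network,
    minimum_driver_set,
    node_importance,
    orient_edges,
    possible_drivers,
    rank_sum_greater,
    synergistic_drivers,
    validate_drivers,
)
from dims.simulate import PlantedModuleSpec, StudyConfig, generate_study

from conftest import make_study


def brute_force_matching_size(arcs) -> int:
    """Exhaustive search over arc subsets forming a matching (each node used
    at most once as tail and once as head)."""
    arcs = list(arcs)
    best = 0

    def rec(i, tails, heads, size):
        nonlocal best
        if size + (len(arcs) - i) <= best:
            return
        if i == len(arcs):
            best = max(best, size)
            return
        rec(i + 1, tails, heads, size)
        t, h = arcs[i]
        if t not in tails and h not in heads:
            rec(i + 1, tails | {t}, heads | {h}, size + 1)

    rec(0, frozenset(), frozenset(), 0)
    return best


def random_digraph(rng, n_max=7, p=0.3):
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    arcs = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return DirectedInteractionNetwork(nodes, arcs)


def controllability_rank(net, drivers, rng, extra_attach=True):
    """Kalman rank with random weights; inputs on the driver nodes.

    Per the minimum-input construction, one existing input is additionally
    attached to one node of every cycle component not reachable from any
    driver (those components need no extra driver node, only a link).
    """
    nodes = net.nodes
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for t, h in net.arcs:
        a[idx[h], idx[t]] = rng.uniform(0.5, 1.5)
    cols = {d: [idx[d]] for d in drivers}
    if extra_attach and drivers:
        g = net.to_digraph()
        reachable = set(drivers)
        for d in drivers:
            reachable |= nx.descendants(g, d)
        unreachable = set(nodes) - reachable
        first = drivers[0]
        for comp in nx.weakly_connected_components(g.subgraph(unreachable)):
            cols[first].append(idx[sorted(comp)[0]])
    b = np.zeros((n, len(drivers)))
    for j, d in enumerate(drivers):
        for i in cols[d]:
            b[i, j] = rng.uniform(0.5, 1.5)
    ctrl = [b]
    power = b
    for _ in range(n - 1):
        power = a @ power
        ctrl.append(power)
    return np.linalg.matrix_rank(np.hstack(ctrl)), n


class TestOrientEdges:
    def test_star_points_outward_from_hub(self):
        edges = [("hub", "a"), ("hub", "b"), ("hub", "c")]
        deg = {"hub": 3, "a": 1, "b": 1, "c": 1}
        arcs = orient_edges(edges, deg)
        assert arcs == [("hub", "a"), ("hub", "b"), ("hub", "c")]

    def test_tie_broken_lexicographically_smaller_is_tail(self):
        assert orient_edges([("b", "a")], {"a": 1, "b": 1}) == [("a", "b")]

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        edges = [(f"n{i}", f"n{j}") for i in range(6) for j in range(i + 1, 6)
                 if rng.random() < 0.6]
        deg = {f"n{i}": int(rng.integers(0, 5)) for i in range(6)}
        assert orient_edges(edges, deg) == orient_edges(list(edges), dict(deg))

    @settings(derandomize=True, max_examples=60)
    @given(
        pairs=st.sets(
            st.tuples(st.integers(0, 8), st.integers(0, 8)).filter(
                lambda t: t[0] < t[1]
            ),
            max_size=20,
        ),
        degs=st.lists(st.integers(0, 10), min_size=9, max_size=9),
    )
    def test_every_edge_oriented_toward_lower_degree(self, pairs, degs):
        edges = [(f"n{i}", f"n{j}") for i, j in pairs]
        degree = {f"n{i}": degs[i] for i in range(9)}
        arcs = orient_edges(edges, degree)
        assert len(arcs) == len(edges)
        for t, h in arcs:
            assert degree[t] > degree[h] or (degree[t] == degree[h] and t < h)


class TestMinimumDriverSet:
    def test_isolated_nodes_are_all_drivers(self):
        net = DirectedInteractionNetwork(["a", "b", "c"], [])
        ds = minimum_driver_set(net)
        assert ds.drivers == ["a", "b", "c"]
        assert ds.n_d == 3

    def test_directed_path_driven_from_its_head(self):
        net = DirectedInteractionNetwork(["1", "2", "3"], [("1", "2"), ("2", "3")])
        ds = minimum_driver_set(net)
        assert ds.matching == [("1", "2"), ("2", "3")]
        assert ds.drivers == ["1"]
        assert ds.n_d == 1

    def test_out_star_needs_hub_plus_all_but_one_leaf(self):
        net = DirectedInteractionNetwork(
            ["hub", "l1", "l2", "l3"],
            [("hub", "l1"), ("hub", "l2"), ("hub", "l3")],
        )
        ds = minimum_driver_set(net)
        assert ds.matching_size == 1
        assert ds.n_d == 3
        assert "hub" in ds.drivers and len(ds.drivers) == 3

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            minimum_driver_set(DirectedInteractionNetwork([], []))

    def test_self_loop_and_duplicate_arcs_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            DirectedInteractionNetwork(["a"], [("a", "a")])
        with pytest.raises(ValueError, match="duplicate"):
            DirectedInteractionNetwork(["a", "b"], [("a", "b"), ("a", "b")])

    def test_matching_is_maximum_on_random_digraphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            net = random_digraph(rng)
            ds = minimum_driver_set(net)
            assert ds.matching_size == brute_force_matching_size(net.arcs)
            assert len(ds.drivers) == ds.n_d

    def test_adding_an_arc_never_increases_driver_count(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            net = random_digraph(rng, p=0.25)
            missing = [
                (u, v)
                for u in net.nodes
                for v in net.nodes
                if u != v and (u, v) not in set(net.arcs)
            ]
            if not missing:
                continue
            extra = missing[int(rng.integers(len(missing)))]
            bigger = DirectedInteractionNetwork(net.nodes, net.arcs + [extra])
            assert minimum_driver_set(bigger).n_d <= minimum_driver_set(net).n_d


class TestControllability:
    def test_identified_drivers_control_random_digraphs(self):
        """Kalman rank test: structural controllability from the minimum
        driver set, over 5 random weight draws per graph."""
        rng = np.random.default_rng(3)
        for _ in range(40):
            net = random_digraph(rng, n_max=6)
            ds = minimum_driver_set(net)
            full = any(
                controllability_rank(net, ds.drivers, rng)[0] == net.n_nodes
                for _ in range(5)
            )
            assert full, (net.arcs, ds.drivers)

    def test_removing_a_driver_breaks_controllability(self):
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(60):
            net = random_digraph(rng, n_max=6, p=0.25)
            ds = minimum_driver_set(net)
            if ds.n_d < 2:
                continue
            checked += 1
            reduced = ds.drivers[1:]
            for _ in range(5):
                rank, n = controllability_rank(net, reduced, rng, extra_attach=False)
                assert rank < n
        assert checked >= 10


class TestPossibleDrivers:
    def test_contains_canonical_drivers(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            net = random_digraph(rng)
            ds = minimum_driver_set(net)
            poss = set(possible_drivers(net))
            if ds.matching_size < net.n_nodes:
                assert set(ds.drivers) <= poss

    def test_unique_matching_gives_unique_driver(self):
        net = DirectedInteractionNetwork(["1", "2", "3"], [("1", "2"), ("2", "3")])
        assert possible_drivers(net) == ["1"]

    def test_alternative_matchings_expand_the_set(self):
        # 1->3 and 2->3: either tail can leave 3 matched; 1 and 2 are always
        # drivers, 3 never (its in-copy is matched in every maximum matching)
        net = DirectedInteractionNetwork(["1", "2", "3"], [("1", "3"), ("2", "3")])
        assert possible_drivers(net) == ["1", "2"]
        # 1->2 and 1->3: one arc usable at a time; 2 and 3 are each avoidable
        net2 = DirectedInteractionNetwork(["1", "2", "3"], [("1", "2"), ("1", "3")])
        assert possible_drivers(net2) == ["1", "2", "3"]

    def test_matches_sampled_matching_union(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            net = random_digraph(rng, p=0.35)
            if minimum_driver_set(net).matching_size == net.n_nodes:
                continue
            union = set()
            for perm in range(40):
                arcs = list(net.arcs)
                rng.shuffle(arcs)
                g = nx.Graph()
                outs = [("out", u) for u in net.nodes]
                g.add_nodes_from(outs)
                g.add_nodes_from([("in", u) for u in net.nodes])
                for t, h in arcs:
                    g.add_edge(("out", t), ("in", h))
                m = nx.bipartite.hopcroft_karp_matching(g, top_nodes=outs)
                heads = {v[1] for u, v in m.items() if u[0] == "out"}
                union |= set(u for u in net.nodes if u not in heads)
            assert union <= set(possible_drivers(net))


def test_synergistic_drivers_intersection_and_warning():
    assert synergistic_drivers({"g1", "g2", "g3"}, {"g2", "g3", "g4"}) == ["g2", "g3"]
    with pytest.warns(UserWarning, match="disjoint"):
        assert synergistic_drivers({"g1"}, {"g2"}) == []


class TestConditionNetwork:
    def test_identical_expression_gives_no_edges(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(6, 5))
        study = make_study({"A": block, "B": block})
        with pytest.warns(UserWarning, match="no edge"):
            net = build_condition_network(study.gene_ids, study, ("A", "B"), 0.5)
        assert net.arcs == []

    def test_impossible_threshold_gives_empty_network(self):
        rng = np.random.default_rng(1)
        study = make_study({"A": rng.normal(size=(6, 5)), "B": rng.normal(size=(6, 5))})
        with pytest.warns(UserWarning, match="no edge"):
            net = build_condition_network(study.gene_ids, study, ("A", "B"), 2.1)
        assert net.arcs == []

    def test_planted_rewired_module_is_densely_connected(self):
        spec = PlantedModuleSpec("m", 20, ("Combo",), loading=0.9)
        cfg = StudyConfig(n_genes=60, module_specs=[spec], deg_fraction=0.0, seed=8)
        study, truth = generate_study(cfg)
        members = truth.module_members["m"]
        net = build_condition_network(members, study, ("Combo", "Vehicle"), 0.5)
        density = len(net.arcs) / (len(members) * (len(members) - 1) / 2)
        background = [g for g in study.gene_ids if g not in members][:20]
        bg_net = build_condition_network(background, study, ("Combo", "Vehicle"), 0.5)
        bg_density = len(bg_net.arcs) / (len(background) * (len(background) - 1) / 2)
        # background pairs pass |delta corr| >= 0.5 by chance (~0.3 at n = 9);
        # the planted module must stand far above that floor
        assert density > bg_density + 0.3

    def test_bidirectional_orientation_doubles_arcs(self):
        rng = np.random.default_rng(2)
        study = make_study({"A": rng.normal(size=(8, 6)), "B": rng.normal(size=(8, 6))})
        net = build_condition_network(study.gene_ids, study, ("A", "B"), 0.4,
                                      orientation="bidirectional")
        assert len(net.arcs) % 2 == 0
        assert set(net.arcs) == {(h, t) for t, h in net.arcs}


class TestNodeImportance:
    def test_path_graph_closed_forms(self):
        net = DirectedInteractionNetwork(["a", "b", "c"], [("b", "a"), ("b", "c")])
        table = node_importance(net)
        assert table.loc["a", "degree_centrality"] == pytest.approx(0.5)
        assert table.loc["b", "degree_centrality"] == pytest.approx(1.0)
        assert table.loc["b", "betweenness"] == pytest.approx(1.0)
        assert table.loc["a", "betweenness"] == pytest.approx(0.0)

    def test_ring_pagerank_is_uniform(self):
        n = 8
        nodes = [f"n{i}" for i in range(n)]
        edges = [(nodes[i], nodes[(i + 1) % n]) for i in range(n)]
        net = DirectedInteractionNetwork(nodes, edges)
        table = node_importance(net)
        np.testing.assert_allclose(table["pagerank"], 1 / n, atol=1e-9)
        assert table["pagerank"].sum() == pytest.approx(1.0)

    def test_betweenness_matches_shortest_path_enumeration(self):
        rng = np.random.default_rng(9)
        nodes = [f"n{i}" for i in range(10)]
        edges = [(nodes[i], nodes[j]) for i in range(10) for j in range(i + 1, 10)
                 if rng.random() < 0.35]
        net = DirectedInteractionNetwork(nodes, orient_edges(edges, {n: 0 for n in nodes}))
        table = node_importance(net)
        g = net.undirected()
        expect = dict.fromkeys(nodes, 0.0)
        for s, t in itertools.combinations(nodes, 2):
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for p in paths:
                for v in p[1:-1]:
                    expect[v] += 1 / len(paths)
        norm = (len(nodes) - 1) * (len(nodes) - 2) / 2
        for v in nodes:
            assert table.loc[v, "betweenness"] == pytest.approx(expect[v] / norm)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            node_importance(DirectedInteractionNetwork(["a"], []))


class TestValidateDrivers:
    @staticmethod
    def table(values, metric_value=None):
        idx = [f"n{i}" for i in range(len(values))]
        data = {m: list(values) for m in
                ("degree_centrality", "eigenvector", "betweenness", "pagerank", "closeness")}
        return pd.DataFrame(data, index=idx)

    def test_exact_p_for_top_ranked_drivers(self):
        """Drivers holding strictly the top 3 of 8 values: p = 1/C(8,3)."""
        table = self.table([8, 7, 6, 5, 4, 3, 2, 1])
        val = validate_drivers(table, {"n0", "n1", "n2"})
        for p in val.p_values.values():
            assert p == pytest.approx(1 / comb(8, 3), rel=1e-9)

    def test_all_tied_values_give_p_one(self):
        table = self.table([2.0] * 10)
        val = validate_drivers(table, {"n0", "n1"})
        assert all(p == 1.0 for p in val.p_values.values())

    def test_degenerate_splits_rejected(self):
        table = self.table([1, 2, 3])
        with pytest.raises(ValueError, match="degenerate"):
            validate_drivers(table, set())
        with pytest.raises(ValueError, match="degenerate"):
            validate_drivers(table, {"n0", "n1", "n2"})

    def test_deciles_are_in_range_and_top_is_ten(self):
        rng = np.random.default_rng(2)
        table = self.table(rng.uniform(size=40))
        val = validate_drivers(table, {"n0", "n1"})
        dec = val.deciles["degree_centrality"]
        assert dec.between(1, 10).all()
        top = table["degree_centrality"].idxmax()
        assert dec[top] == 10

    def test_null_rank_sum_p_is_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            x = rng.normal(size=6)
            y = rng.normal(size=8)
            ps.append(rank_sum_greater(x, y))
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
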
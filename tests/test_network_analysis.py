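"""Weighted residue network: contacts, shortest paths, betweenness,
modularity, Girvan-Newman and community graphs."""

from __future__ import annotations

import numpy as np
import pytest

import allopath as ap
from allopath.errors import CongruenceError

from .conftest import bead_ensemble, random_weighted_network, toy_network
from .oracles import (
    brute_edge_betweenness,
    dijkstra_distances,
    exhaustive_max_modularity,
)


def N(i):
    return ("A", i)


class TestContactGraph:
    def _static_ensemble(self, coords, n_frames=8):
        return bead_ensemble(np.tile(np.asarray(coords, float), (n_frames, 1, 1)))

    def test_persistent_contact_kept(self):
        # residues 1 and 3 fixed 5 Å apart, far third bead in between by index
        ens = self._static_ensemble([[0, 0, 0], [50, 0, 0], [5.0, 0, 0]])
        g = ap.build_contact_graph(ens, cutoff=8.0, persistence=0.75)
        assert g.persistence[(N(1), N(3))] == 1.0

    def test_intermittent_contact_dropped(self):
        coords = np.tile(np.array([[0.0, 0, 0], [50, 0, 0], [5.0, 0, 0]]),
                         (10, 1, 1))
        coords[4:, 2, 0] = 30.0  # in contact only 40% of frames
        g = ap.build_contact_graph(bead_ensemble(coords), cutoff=8.0,
                                   persistence=0.75)
        assert (N(1), N(3)) not in g.persistence

    def test_sequence_neighbors_excluded(self):
        ens = self._static_ensemble([[0, 0, 0], [3.8, 0, 0], [50, 0, 0]])
        g = ap.build_contact_graph(ens, cutoff=8.0, exclude_neighbors=1)
        assert (N(1), N(2)) not in g.persistence
        g2 = ap.build_contact_graph(ens, cutoff=8.0, exclude_neighbors=0)
        assert (N(1), N(2)) in g2.persistence


class TestWeightEdges:
    def test_perfect_correlation_zero_length(self):
        g = ap.ContactGraph([N(1), N(3)], {(N(1), N(3)): 1.0})
        dccm = ap.CorrelationMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]),
                                    [N(1), N(3)])
        net = ap.weight_edges(g, dccm)
        assert net.edges[(N(1), N(3))]["length"] == 0.0

    def test_log_length_value(self):
        g = ap.ContactGraph([N(1), N(3)], {(N(1), N(3)): 1.0})
        dccm = ap.CorrelationMatrix(np.array([[1.0, 0.1], [0.1, 1.0]]),
                                    [N(1), N(3)])
        net = ap.weight_edges(g, dccm)
        assert np.isclose(net.edges[(N(1), N(3))]["length"], 2.302585092994046)

    def test_monotone_in_coupling(self, rng):
        net = random_weighted_network(rng, 8)
        for e1 in net.edges:
            for e2 in net.edges:
                c1, c2 = net.coupling(e1), net.coupling(e2)
                if c1 > c2:
                    assert net.edges[e1]["length"] < net.edges[e2]["length"]

    def test_floor_drops_uncorrelated_edges(self):
        g = ap.ContactGraph([N(1), N(3)], {(N(1), N(3)): 1.0})
        dccm = ap.CorrelationMatrix(np.array([[1.0, 1e-6], [1e-6, 1.0]]),
                                    [N(1), N(3)])
        net = ap.weight_edges(g, dccm)
        assert not net.edges

    def test_missing_label_rejected(self):
        g = ap.ContactGraph([N(1), N(9)], {(N(1), N(9)): 1.0})
        dccm = ap.CorrelationMatrix(np.eye(2), [N(1), N(3)])
        with pytest.raises(CongruenceError):
            ap.weight_edges(g, dccm)


class TestShortestPaths:
    def test_triangle_detour(self):
        net = toy_network({(1, 2): np.exp(-1.0), (2, 3): np.exp(-1.0),
                           (1, 3): np.exp(-2.5)})
        pm = ap.shortest_paths(net)
        i, j = pm.nodes.index(N(1)), pm.nodes.index(N(3))
        assert np.isclose(pm.dist[i, j], 2.0)

    def test_single_edge(self):
        net = toy_network({(1, 2): 0.5})
        pm = ap.shortest_paths(net)
        assert np.isclose(pm.dist[0, 1], -np.log(0.5))

    def test_tie_counting(self):
        # 4-cycle with equal lengths: two co-optimal paths across the diagonal
        w = np.exp(-1.0)
        net = toy_network({(1, 2): w, (2, 3): w, (3, 4): w, (1, 4): w})
        pm = ap.shortest_paths(net)
        i, j = pm.nodes.index(N(1)), pm.nodes.index(N(3))
        assert np.isclose(pm.dist[i, j], 2.0)
        assert pm.counts[i, j] == 2

    def test_matches_dijkstra_oracle_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 16))
            net = random_weighted_network(rng, n, p=0.35,
                                          ensure_connected=False)
            pm = ap.shortest_paths(net)
            lengths = {e: a["length"] for e, a in net.edges.items()}
            oracle = dijkstra_distances(pm.nodes, lengths)
            for i, u in enumerate(pm.nodes):
                for j, v in enumerate(pm.nodes):
                    d = oracle[(u, v)]
                    if np.isinf(d):
                        assert np.isinf(pm.dist[i, j])
                    else:
                        assert abs(pm.dist[i, j] - d) < 1e-12

    def test_triangle_inequality(self, rng):
        net = random_weighted_network(rng, 12)
        pm = ap.shortest_paths(net)
        d = pm.dist
        n = len(pm.nodes)
        for k in range(n):
            assert np.all(d <= d[:, k][:, None] + d[k, :][None, :] + 1e-9)


class TestEdgeBetweenness:
    def test_path_graph_middle_edge(self):
        w = np.exp(-1.0)
        net = toy_network({(1, 2): w, (2, 3): w, (3, 4): w})
        bt = ap.edge_betweenness(net)
        assert np.isclose(bt.values[(N(2), N(3))], 4.0)
        assert np.isclose(bt.values[(N(1), N(2))], 3.0)

    def test_symmetric_cycle_uniform(self):
        w = np.exp(-1.0)
        net = toy_network({(1, 2): w, (2, 3): w, (3, 4): w, (1, 4): w})
        bt = ap.edge_betweenness(net)
        vals = list(bt.values.values())
        np.testing.assert_allclose(vals, vals[0])

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 11))
            net = random_weighted_network(rng, n, p=0.35,
                                          ensure_connected=False)
            bt = ap.edge_betweenness(net)
            lengths = {e: a["length"] for e, a in net.edges.items()}
            oracle = brute_edge_betweenness(net.nodes, lengths)
            for e in lengths:
                assert abs(bt.values[e] - oracle[e]) < 1e-9

    def test_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        net = random_weighted_network(rng, 12, p=0.3)
        G = nx.Graph()
        for (u, v), a in net.edges.items():
            G.add_edge(u, v, weight=a["length"])
        ref = nx.edge_betweenness_centrality(G, weight="weight",
                                             normalized=False)
        bt = ap.edge_betweenness(net)
        for e, val in bt.values.items():
            nx_val = ref.get(e, ref.get((e[1], e[0])))
            assert abs(val - nx_val) < 1e-9

    def test_tree_betweenness_sums_to_path_lengths(self, rng):
        # spanning-tree identity: total betweenness == total pair path length
        corr = {(1, 2): 0.5, (2, 3): 0.7, (2, 4): 0.3, (4, 5): 0.9,
                (4, 6): 0.4}
        net = toy_network(corr)
        bt = ap.edge_betweenness(net)
        pm = ap.shortest_paths(net)
        # count edges per pair path by rerunning distances on unit lengths
        unit = ap.WeightedNetwork(net.nodes, {
            e: {"length": 1.0, "corr": a["corr"], "persistence": 1.0}
            for e, a in net.edges.items()})
        hops = ap.shortest_paths(unit)
        total_hops = hops.dist[np.triu_indices(len(net.nodes), 1)].sum()
        assert np.isclose(sum(bt.values.values()), total_hops)


class TestModularity:
    def _clique_pair(self, bridge=False):
        corr = {}
        for base in (0, 4):
            for i in range(1 + base, 5 + base):
                for j in range(i + 1, 5 + base):
                    corr[(i, j)] = 0.5
        if bridge:
            corr[(4, 5)] = 0.5
        return toy_network(corr)

    def test_single_community_is_zero(self):
        net = self._clique_pair(bridge=True)
        part = {n: 0 for n in net.nodes}
        assert ap.modularity(net, part) == pytest.approx(0.0, abs=1e-15)

    def test_two_disconnected_cliques_half(self):
        net = self._clique_pair(bridge=False)
        part = {n: 0 if n[1] <= 4 else 1 for n in net.nodes}
        assert ap.modularity(net, part) == pytest.approx(0.5)

    def test_uncovered_node_rejected(self):
        net = self._clique_pair()
        with pytest.raises(CongruenceError):
            ap.modularity(net, {net.nodes[0]: 0})

    def test_girvan_newman_matches_exhaustive_search(self, rng):
        """On small two-community graphs the greedy max-Q partition equals
        the global exhaustive-search optimum."""
        for _ in range(8):
            corr = {}
            for base, size in ((0, 4), (4, 4)):
                ids = range(1 + base, 1 + base + size)
                for i in ids:
                    for j in ids:
                        if i < j:
                            corr[(i, j)] = float(rng.uniform(0.5, 0.95))
            corr[(4, 5)] = float(rng.uniform(0.05, 0.2))
            net = toy_network(corr)
            part = ap.girvan_newman(net)
            weights = {e: abs(a["corr"]) for e, a in net.edges.items()}
            best_q, best_p = exhaustive_max_modularity(net.nodes, weights)
            assert part.q == pytest.approx(best_q, abs=1e-9)
            got = {frozenset(m) for m in part.communities().values()}
            want = {frozenset(grp) for grp in best_p}
            assert got == want


class TestGirvanNewman:
    def test_bridged_cliques_split_at_bridge(self):
        corr = {}
        for base in (0, 4):
            for i in range(1 + base, 5 + base):
                for j in range(i + 1, 5 + base):
                    corr[(i, j)] = 0.8
        corr[(4, 5)] = 0.1
        part = ap.girvan_newman(toy_network(corr))
        comms = {frozenset(m) for m in part.communities().values()}
        assert comms == {frozenset(N(i) for i in range(1, 5)),
                         frozenset(N(i) for i in range(5, 9))}

    def test_disconnected_components_returned(self):
        corr = {(1, 2): 0.8, (2, 3): 0.8, (5, 6): 0.8, (6, 7): 0.8}
        part = ap.girvan_newman(toy_network(corr))
        comms = {frozenset(m) for m in part.communities().values()}
        assert frozenset({N(1), N(2), N(3)}) in comms
        assert frozenset({N(5), N(6), N(7)}) in comms

    def test_node_order_invariance(self, rng):
        net = random_weighted_network(rng, 10, p=0.35)
        p1 = ap.girvan_newman(net)
        shuffled = ap.WeightedNetwork(
            list(reversed(net.nodes)),
            dict(sorted(net.edges.items(), reverse=True)))
        p2 = ap.girvan_newman(shuffled)
        assert p1.labels == p2.labels
        assert p1.q == pytest.approx(p2.q, abs=1e-12)


class TestMergeCommunities:
    def _setup(self):
        corr = {(1, 2): 0.8, (1, 3): 0.8, (2, 3): 0.8,
                (4, 5): 0.8, (4, 6): 0.8, (5, 6): 0.8,
                (3, 4): 0.2, (6, 7): 0.6, (7, 8): 0.7}
        net = toy_network(corr)
        part = ap.girvan_newman(net)
        return net, part

    def test_identity_plan_unchanged(self):
        net, part = self._setup()
        same = ap.merge_communities(part, net,
                                    plan={c: c for c in set(part.labels.values())})
        assert same.labels == part.labels
        assert same.q == pytest.approx(part.q)

    def test_merge_all_gives_q_zero(self):
        net, part = self._setup()
        merged = ap.merge_communities(
            part, net, plan={c: 0 for c in set(part.labels.values())})
        assert merged.n_communities() == 1
        assert merged.q == pytest.approx(0.0, abs=1e-15)

    def test_min_size_absorbs_small_community(self):
        net, part = self._setup()
        merged = ap.merge_communities(part, net, min_size=3)
        sizes = [len(m) for m in merged.communities().values()]
        assert all(s >= 3 for s in sizes)
        assert merged.merge_history

    def test_unknown_label_rejected(self):
        net, part = self._setup()
        with pytest.raises(CongruenceError):
            ap.merge_communities(part, net, plan={99: 0})


class TestCommunityGraph:
    def test_ball_sizes(self):
        corr = {(i, j): 0.5 for i in range(1, 11) for j in range(i + 1, 11)}
        net = toy_network(corr)
        labels = {N(i): (0 if i <= 6 else 1) for i in range(1, 11)}
        part = ap.CommunityPartition(labels, 0.0)
        bt = ap.edge_betweenness(net)
        g = ap.community_graph(net, part, bt)
        assert g.balls == {0: 6, 1: 4}

    def test_no_cross_edges_no_stick(self):
        corr = {(1, 2): 0.8, (3, 4): 0.8}
        net = toy_network(corr)
        labels = {N(1): 0, N(2): 0, N(3): 1, N(4): 1}
        g = ap.community_graph(net, ap.CommunityPartition(labels, 0.0),
                               ap.edge_betweenness(net))
        assert g.sticks == {}

    def test_path_graph_split_stick_equals_edge_betweenness(self):
        w = np.exp(-1.0)
        net = toy_network({(1, 2): w, (2, 3): w, (3, 4): w})
        labels = {N(1): 0, N(2): 0, N(3): 1, N(4): 1}
        g = ap.community_graph(net, ap.CommunityPartition(labels, 0.0),
                               ap.edge_betweenness(net))
        assert g.sticks == {(0, 1): pytest.approx(4.0)}

    def test_exclusion_list_applied(self):
        w = np.exp(-1.0)
        net = toy_network({(1, 2): w, (2, 3): w, (3, 4): w})
        labels = {N(1): 0, N(2): 0, N(3): 1, N(4): 1}
        g = ap.community_graph(net, ap.CommunityPartition(labels, 0.0),
                               ap.edge_betweenness(net),
                               exclude_nodes={N(4)})
        assert g.balls == {0: 2, 1: 1}


class TestCompareNetworks:
    def _graph(self, sticks):
        return ap.CommunityGraph({0: 5, 1: 5, 2: 5}, sticks)

    def test_self_comparison_zero(self):
        g = self._graph({(0, 1): 10.0, (1, 2): 5.0})
        assert all(v == 0.0 for _, v in ap.compare_networks(g, g))

    def test_antisymmetric(self):
        a = self._graph({(0, 1): 10.0, (1, 2): 5.0})
        b = self._graph({(0, 1): 4.0, (1, 2): 9.0})
        fwd = dict(ap.compare_networks(a, b))
        rev = dict(ap.compare_networks(b, a))
        for k in fwd:
            assert fwd[k] == -rev[k]

    def test_unmapped_community_rejected(self):
        a = self._graph({(0, 1): 1.0})
        b = ap.CommunityGraph({7: 5}, {(7, 7): 0.0})
        b.sticks = {(7, 8): 1.0}
        with pytest.raises(CongruenceError):
            ap.compare_networks(a, b)
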
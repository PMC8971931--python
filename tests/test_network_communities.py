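import itertools

import networkx as nx
import numpy as np
import pytest

from allostate.dccm import CorrelationMatrix
from allostate.network_communities import (
    ResidueGraph,
    community_connectivity,
    contact_occupancy_edges,
    edge_betweenness,
    edge_distances,
    floyd_warshall_paths,
    girvan_newman_communities,
)
from allostate.traj_io import Ensemble


def make_graph(edges):
    """Build a ResidueGraph from (u, v, distance) triples."""
    G = nx.Graph()
    for u, v, d in edges:
        G.add_edge(u, v, distance=d, correlation=np.exp(-d), occupancy=1.0)
    return ResidueGraph(graph=G)


def exhaustive_shortest(G, s, t):
    """All simple paths oracle: (min distance, number of co-optimal paths)."""
    best, count = np.inf, 0
    for path in nx.all_simple_paths(G, s, t):
        d = sum(G[a][b]["distance"] for a, b in zip(path, path[1:]))
        if d < best - 1e-12:
            best, count = d, 1
        elif abs(d - best) <= 1e-12:
            count += 1
    return best, count


def exhaustive_edge_betweenness(G):
    """Fractional betweenness oracle by explicit path enumeration."""
    bc = {tuple(sorted(e)): 0.0 for e in G.edges}
    nodes = sorted(G.nodes)
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(G, s, t):
            continue
        paths, best = [], np.inf
        for path in nx.all_simple_paths(G, s, t):
            d = sum(G[a][b]["distance"] for a, b in zip(path, path[1:]))
            if d < best - 1e-12:
                best, paths = d, [path]
            elif abs(d - best) <= 1e-12:
                paths.append(path)
        for path in paths:
            for a, b in zip(path, path[1:]):
                bc[tuple(sorted((a, b)))] += 1.0 / len(paths)
    return bc


def exhaustive_best_partition(G, weight="correlation"):
    """Maximum-modularity partition over all set partitions (n <= 8)."""

    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {first}] + part[i + 1 :]
            yield part + [{first}]

    best_q, best = -np.inf, None
    for part in partitions(sorted(G.nodes)):
        q = nx.algorithms.community.modularity(G, part, weight=weight)
        if q > best_q:
            best_q, best = q, part
    return best_q, best


def two_clique_bridge():
    G = nx.Graph()
    for base in (0, 4):
        for u, v in itertools.combinations(range(base, base + 4), 2):
            G.add_edge(u, v, distance=1.0, correlation=0.9, occupancy=1.0)
    G.add_edge(3, 4, distance=1.0, correlation=0.9, occupancy=1.0)
    return ResidueGraph(graph=G)


class TestContactOccupancy:
    def make_two_residue_ensemble(self, distances):
        frames = []
        for d in distances:
            frames.append([[0.0, 0.0, 0.0], [50.0, 0, 0], [d, 0.0, 100.0]])
        return Ensemble(
            coordinates=np.array(frames), residue_index=np.arange(3)
        )

    def test_constant_contact_has_full_occupancy(self):
        ens = self.make_two_residue_ensemble([4.0] * 10)
        edges = contact_occupancy_edges(ens)
        assert edges == {}  # (0,2) at z-distance 100; (0,1) at 50; none close
        ens2 = Ensemble(
            coordinates=np.tile(
                np.array([[0.0, 0, 0], [50.0, 0, 0], [4.0, 0, 0]]), (10, 1, 1)
            ),
            residue_index=np.arange(3),
        )
        assert contact_occupancy_edges(ens2) == {(0, 2): 1.0}

    def test_seventy_percent_occupancy_below_threshold_no_edge(self):
        dists = [4.0] * 7 + [6.0] * 3  # 0.70 < 0.75
        coords = np.array([[[0.0, 0, 0], [50.0, 0, 0], [d, 0, 0]] for d in dists])
        ens = Ensemble(coordinates=coords, residue_index=np.arange(3))
        assert (0, 2) not in contact_occupancy_edges(ens)

    def test_exactly_seventy_five_percent_is_an_edge(self):
        """'at least 75%' — the boundary is inclusive."""
        dists = [4.0] * 6 + [6.0] * 2  # exactly 0.75
        coords = np.array([[[0.0, 0, 0], [50.0, 0, 0], [d, 0, 0]] for d in dists])
        ens = Ensemble(coordinates=coords, residue_index=np.arange(3))
        assert contact_occupancy_edges(ens) == {(0, 2): 0.75}

    def test_sequence_neighbors_excluded(self):
        coords = np.tile(np.array([[0.0, 0, 0], [4.0, 0, 0]]), (5, 1, 1))
        ens = Ensemble(coordinates=coords, residue_index=np.arange(2))
        assert contact_occupancy_edges(ens) == {}
        assert contact_occupancy_edges(ens, exclude_neighbors=0) == {(0, 1): 1.0}

    def test_invalid_parameters_rejected(self):
        ens = self.make_two_residue_ensemble([4.0])
        with pytest.raises(ValueError):
            contact_occupancy_edges(ens, cutoff=-1.0)
        with pytest.raises(ValueError):
            contact_occupancy_edges(ens, min_occupancy=1.5)


class TestEdgeDistances:
    def make_C(self, c01):
        M = np.eye(3)
        M[0, 1] = M[1, 0] = c01
        return CorrelationMatrix(values=M, residue_ids=np.arange(3))

    @pytest.mark.parametrize(
        "c,expected",
        [(1.0, 0.0), (0.1, 2.302585092994046), (np.exp(-1.0), 1.0)],
    )
    def test_closed_form_distances(self, c, expected):
        g = edge_distances(self.make_C(c), {(0, 1): 1.0})
        assert g.graph[0][1]["distance"] == pytest.approx(expected, abs=1e-12)

    def test_zero_correlation_edge_dropped_and_reported(self):
        with pytest.warns(UserWarning, match="dropped"):
            g = edge_distances(self.make_C(0.0), {(0, 1): 1.0})
        assert g.dropped_edges == [(0, 1)]
        assert g.graph.number_of_edges() == 0


class TestFloydWarshall:
    def test_triangle_takes_two_hops(self):
        g = make_graph([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 3.0)])
        nodes, D, N = floyd_warshall_paths(g)
        i, j = nodes.index(0), nodes.index(2)
        assert D[i, j] == pytest.approx(2.0)
        assert N[i, j] == 1

    def test_single_edge(self):
        g = make_graph([(0, 1, 0.7)])
        _, D, _ = floyd_warshall_paths(g)
        assert D[0, 1] == pytest.approx(0.7)

    def test_unreachable_pairs_infinite(self):
        g = make_graph([(0, 1, 1.0), (2, 3, 1.0)])
        nodes, D, N = floyd_warshall_paths(g)
        i, j = nodes.index(0), nodes.index(3)
        assert np.isinf(D[i, j]) and N[i, j] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
        for u, v in G.edges:
            G[u][v]["distance"] = round(float(rng.uniform(0.5, 3.0)), 3)
            G[u][v]["correlation"] = 0.5
            G[u][v]["occupancy"] = 1.0
        g = ResidueGraph(graph=G)
        nodes, D, N = floyd_warshall_paths(g)
        for a, b in itertools.combinations(range(len(nodes)), 2):
            s, t = nodes[a], nodes[b]
            if nx.has_path(G, s, t):
                d, c = exhaustive_shortest(G, s, t)
                assert D[a, b] == pytest.approx(d, abs=1e-9)
                assert N[a, b] == c
            else:
                assert np.isinf(D[a, b])

    def test_matches_dijkstra_all_sources(self):
        G = nx.gnp_random_graph(8, 0.5, seed=17)
        rng = np.random.default_rng(17)
        for u, v in G.edges:
            G[u][v]["distance"] = float(rng.uniform(0.5, 3.0))
            G[u][v]["correlation"] = 0.5
            G[u][v]["occupancy"] = 1.0
        nodes, D, _ = floyd_warshall_paths(ResidueGraph(graph=G))
        dij = dict(nx.all_pairs_dijkstra_path_length(G, weight="distance"))
        for a, s in enumerate(nodes):
            for b, t in enumerate(nodes):
                expect = dij[s].get(t, np.inf)
                assert D[a, b] == pytest.approx(expect, abs=1e-9)

    def test_negative_distance_rejected(self):
        G = nx.Graph()
        G.add_edge(0, 1, distance=-0.1, correlation=0.5, occupancy=1.0)
        with pytest.raises(ValueError, match="negative"):
            ResidueGraph(graph=G)


class TestEdgeBetweenness:
    def test_path_graph_hand_enumeration(self):
        g = make_graph([("a", "b", 1.0), ("b", "c", 1.0)])
        bc = edge_betweenness(g)
        assert bc[("a", "b")] == pytest.approx(2.0)  # pairs ab, ac
        assert bc[("b", "c")] == pytest.approx(2.0)

    def test_bridge_has_strictly_largest_betweenness(self):
        g = two_clique_bridge()
        bc = edge_betweenness(g)
        bridge = bc[(3, 4)]
        assert all(v < bridge for e, v in bc.items() if e != (3, 4))

    def test_disconnected_pair_of_edges(self):
        g = make_graph([(0, 1, 1.0), (2, 3, 1.0)])
        bc = edge_betweenness(g)
        assert bc[(0, 1)] == pytest.approx(1.0)
        assert bc[(2, 3)] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_fractional_mode_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        G = nx.gnp_random_graph(7, 0.45, seed=seed)
        for u, v in G.edges:
            G[u][v]["distance"] = round(float(rng.uniform(0.5, 2.0)), 3)
            G[u][v]["correlation"] = 0.5
            G[u][v]["occupancy"] = 1.0
        if G.number_of_edges() == 0:
            pytest.skip("empty random draw")
        bc = edge_betweenness(ResidueGraph(graph=G))
        oracle = exhaustive_edge_betweenness(G)
        for e, v in oracle.items():
            assert bc[e] == pytest.approx(v, abs=1e-8)

    def test_integer_mode_counts_co_optimal_paths_integrally(self):
        # square: two co-optimal 2-hop paths between opposite corners
        g = make_graph([(0, 1, 1.0), (1, 2, 1.0), (0, 3, 1.0), (3, 2, 1.0)])
        frac = edge_betweenness(g)
        integer = edge_betweenness(g, mode="integer")
        # edge (0,1) carries: pair (0,1) directly, and one of the two
        # co-optimal paths for each of pairs (0,2) and (1,3) — half a unit
        # each in fractional mode, a full unit each in integer mode
        assert frac[(0, 1)] == pytest.approx(1.0 + 0.5 + 0.5)
        assert integer[(0, 1)] == pytest.approx(1.0 + 1.0 + 1.0)

    def test_conservation_identity_on_random_trees(self):
        """On a tree shortest paths are unique: total betweenness equals
        the total number of (pair, edge-on-path) incidences."""
        for seed in range(4):
            T = nx.random_labeled_tree(9, seed=seed)
            rng = np.random.default_rng(seed)
            for u, v in T.edges:
                T[u][v]["distance"] = float(rng.uniform(0.5, 2.0))
                T[u][v]["correlation"] = 0.5
                T[u][v]["occupancy"] = 1.0
            bc = edge_betweenness(ResidueGraph(graph=T))
            total = sum(bc.values())
            expect = sum(
                nx.shortest_path_length(T, s, t)
                for s, t in itertools.combinations(T.nodes, 2)
            )
            assert total == pytest.approx(expect, abs=1e-8)


class TestGirvanNewman:
    def test_two_cliques_recovered_and_match_exhaustive_partition(self):
        g = two_clique_bridge()
        part = girvan_newman_communities(g, min_size=3)
        comms = sorted(sorted(c) for c in part.communities)
        assert comms == [[0, 1, 2, 3], [4, 5, 6, 7]]
        q_best, best = exhaustive_best_partition(g.graph)
        assert part.modularity == pytest.approx(q_best, abs=1e-9)
        assert sorted(sorted(c) for c in best) == comms

    def test_complete_graph_stays_one_community(self):
        G = nx.complete_graph(5)
        for u, v in G.edges:
            G[u][v].update(distance=1.0, correlation=0.8, occupancy=1.0)
        part = girvan_newman_communities(ResidueGraph(graph=G), min_size=3)
        assert [sorted(c) for c in part.communities] == [[0, 1, 2, 3, 4]]
        q_best, best = exhaustive_best_partition(G)
        assert part.modularity == pytest.approx(q_best, abs=1e-9)

    def test_small_communities_discarded_and_flagged(self):
        g = two_clique_bridge()
        # append an isolated 2-node appendage
        g.graph.add_edge(10, 11, distance=1.0, correlation=0.9, occupancy=1.0)
        with pytest.warns(UserWarning, match="discarded"):
            part = girvan_newman_communities(ResidueGraph(graph=g.graph), min_size=3)
        assert {10, 11} in part.discarded
        assert all(len(c) >= 3 for c in part.communities)

    def test_modularity_of_reported_split_nonnegative(self):
        g = two_clique_bridge()
        part = girvan_newman_communities(g)
        assert part.modularity >= 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            girvan_newman_communities(ResidueGraph(graph=nx.Graph()))

    def test_planted_two_domain_recovery_end_to_end(self, two_domain_system):
        """Ensemble → DCCM → occupancy edges → communities recovers the
        planted domain labels on ≥95% of residues."""
        from allostate.dccm import cross_correlation_matrix

        spec, ens, _ = two_domain_system
        C = cross_correlation_matrix(ens)
        edges = contact_occupancy_edges(ens)
        graph = edge_distances(C, edges)
        part = girvan_newman_communities(graph, min_size=3)
        labels = part.labels()
        agree = 0
        for cid, comm in enumerate(part.communities):
            votes = np.bincount([spec.domain_labels[r] for r in comm])
            agree += votes.max()
        assert agree / spec.n_residues >= 0.95
        assert all(len(c) >= 3 for c in part.communities)


class TestCommunityConnectivity:
    def test_no_inter_community_edges_all_zero(self):
        g = make_graph([(0, 1, 1.0), (1, 2, 1.0), (3, 4, 1.0), (4, 5, 1.0)])
        conn = community_connectivity([{0, 1, 2}, {3, 4, 5}], g)
        assert conn == {}

    def test_bridge_weight_equals_bridge_betweenness(self):
        g = two_clique_bridge()
        bc = edge_betweenness(g)
        conn = community_connectivity([{0, 1, 2, 3}, {4, 5, 6, 7}], g)
        assert conn[(0, 1)] == pytest.approx(bc[(3, 4)])

    def test_merging_communities_conserves_total_betweenness(self):
        g = two_clique_bridge()
        bc = edge_betweenness(g)
        total = sum(bc.values())
        split = community_connectivity([{0, 1, 2, 3}, {4, 5, 6, 7}], g)
        merged = community_connectivity([{0, 1, 2, 3, 4, 5, 6, 7}], g)
        assert merged == {}  # all edges internal after the merge
        internal_split = total - sum(split.values())
        assert internal_split + sum(split.values()) == pytest.approx(total)

    def test_overlapping_communities_rejected(self):
        g = two_clique_bridge()
        with pytest.raises(ValueError, match="overlap"):
            community_connectivity([{0, 1, 2, 3}, {3, 4, 5}], g)
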
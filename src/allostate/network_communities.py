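"""Residue-interaction networks and Girvan–Newman community decomposition.

Nodes are residues; an edge joins residues that remain within a contact
cutoff (4.5 Å by default) for at least a minimum fraction of frames
(75% by default), with sequence neighbours excluded.  Edge length is
``d_ij = -ln|C_ij|`` so that strongly correlated contacts are short,
making shortest paths the most-correlated communication routes.

Communities come from the Girvan–Newman divisive algorithm: the current
maximum-betweenness edge is removed (betweenness recomputed each step)
until full fragmentation, and the partition of maximum Newman–Girvan
modularity along the removal trace is reported.  Connectivity between
communities is the summed betweenness of the original-graph edges that
cross them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dccm import CorrelationMatrix
from .traj_io import Ensemble

__all__ = [
    "ResidueGraph",
    "CommunityPartition",
    "contact_occupancy_edges",
    "edge_distances",
    "floyd_warshall_paths",
    "edge_betweenness",
    "girvan_newman_communities",
    "community_connectivity",
]

_TIE_TOL = 1e-12


@dataclass
class ResidueGraph:
    """Weighted simple graph over residues.

    Each edge carries ``occupancy`` (contact fraction), ``correlation``
    (|C_ij|, the affinity weight used for modularity) and ``distance``
    (-ln|C_ij|, the cost weight used for paths and betweenness).
    """

    graph: nx.Graph
    dropped_edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-loops are not allowed")
            if data.get("distance", 0.0) < 0:
                raise ValueError(f"negative edge distance on ({u},{v})")

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)


@dataclass
class CommunityPartition:
    communities: list[set[int]]  # reported communities (>= min_size), sorted
    modularity: float
    connectivity: dict[tuple[int, int], float]
    removal_trace: list[tuple[int, int]]
    discarded: list[set[int]] = field(default_factory=list)
    all_communities: list[set[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for comm in self.all_communities or self.communities:
            if seen & comm:
                raise ValueError("communities must be disjoint")
            seen |= comm
        if not (-0.5 - 1e-9 <= self.modularity <= 1.0 + 1e-9):
            raise ValueError("modularity out of range")

    def labels(self) -> dict[int, int]:
        """Residue -> community id (index into :attr:`communities`)."""
        out: dict[int, int] = {}
        for cid, comm in enumerate(self.communities):
            for node in comm:
                out[node] = cid
        return out


# --- contact map ----------------------------------------------------------


def contact_occupancy_edges(
    ensemble: Ensemble,
    cutoff: float = 4.5,
    min_occupancy: float = 0.75,
    exclude_neighbors: int = 1,
) -> dict[tuple[int, int], float]:
    """Candidate edges from contact occupancy.

    Edge (i, j) exists iff the minimum inter-residue atom distance is
    ≤ ``cutoff`` in at least ``min_occupancy`` of frames (boundary
    inclusive) and |i - j| > ``exclude_neighbors`` along the chain.
    Uses the minimum distance over all atom pairs of the two residues;
    for one-bead-per-residue models this reduces to the Cα distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (0.0 < min_occupancy <= 1.0):
        raise ValueError("min_occupancy must lie in (0, 1]")
    n_res = ensemble.n_residues
    n_frames = ensemble.n_frames
    one_bead = ensemble.n_particles == n_res

    counts = np.zeros((n_res, n_res), dtype=np.int64)
    if one_bead:
        if ensemble.n_particles > 1 and np.any(np.diff(ensemble.residue_index) != 1):
            warnings.warn(
                "one particle per residue: contacts use Cα distances", stacklevel=2
            )
        # chunk over frames to bound memory at ~n_res^2 * chunk doubles
        chunk = max(1, int(2e7 // max(n_res * n_res, 1)))
        for lo in range(0, n_frames, chunk):
            x = ensemble.coordinates[lo : lo + chunk]
            diff = x[:, :, None, :] - x[:, None, :, :]
            d2 = np.einsum("fija,fija->fij", diff, diff)
            counts += (d2 <= cutoff * cutoff).sum(axis=0)
    else:
        atoms = [ensemble.residue_atoms(r) for r in range(n_res)]
        for i in range(n_res):
            for j in range(i + 1, n_res):
                xi = ensemble.coordinates[:, atoms[i], :]
                xj = ensemble.coordinates[:, atoms[j], :]
                diff = xi[:, :, None, :] - xj[:, None, :, :]
                d2 = np.einsum("fabx,fabx->fab", diff, diff).min(axis=(1, 2))
                counts[i, j] = counts[j, i] = int((d2 <= cutoff * cutoff).sum())

    edges: dict[tuple[int, int], float] = {}
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if j - i <= exclude_neighbors:
                continue
            occ = counts[i, j] / n_frames
            if occ >= min_occupancy:
                edges[(i, j)] = occ
    return edges


def edge_distances(
    C: CorrelationMatrix, edges: dict[tuple[int, int], float]
) -> ResidueGraph:
    """Attach -ln|C| distances to contact edges; zero-correlation edges
    (infinite distance) are dropped and reported."""
    G = nx.Graph()
    dropped: list[tuple[int, int]] = []
    ids = list(C.residue_ids)
    pos = {rid: k for k, rid in enumerate(ids)}
    for (i, j), occ in sorted(edges.items()):
        cij = C.values[pos[i], pos[j]]
        if np.isnan(cij):
            raise ValueError(f"edge ({i},{j}) has undefined correlation")
        a = abs(float(cij))
        if a > 1 + 1e-10:
            raise ValueError(f"|C| > 1 on edge ({i},{j})")
        if a == 0.0:
            dropped.append((i, j))
            continue
        G.add_edge(i, j, occupancy=occ, correlation=a, distance=-np.log(min(a, 1.0)))
    if dropped:
        warnings.warn(
            f"{len(dropped)} edges dropped (zero correlation, infinite distance)",
            stacklevel=2,
        )
    return ResidueGraph(graph=G, dropped_edges=dropped)


# --- shortest paths and betweenness ---------------------------------------


def floyd_warshall_paths(
    graph: ResidueGraph,
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """All-pairs shortest distances with co-optimal path counts.

    Returns ``(nodes, D, N)``: D[a, b] is the shortest distance between
    nodes[a] and nodes[b] (inf when unreachable), N[a, b] the number of
    distinct shortest paths (0 when unreachable).  Ties in length are
    detected with a small absolute/relative tolerance.
    """
    nodes = graph.nodes
    n = len(nodes)
    pos = {v: k for k, v in enumerate(nodes)}
    D = np.full((n, n), np.inf)
    N = np.zeros((n, n), dtype=np.float64)
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(N, 1.0)
    for u, v, data in graph.graph.edges(data=True):
        w = float(data["distance"])
        if w < 0:
            raise ValueError("negative edge distance")
        a, b = pos[u], pos[v]
        if w < D[a, b]:
            D[a, b] = D[b, a] = w
            N[a, b] = N[b, a] = 1.0
    for k in range(n):
        for i in range(n):
            if not np.isfinite(D[i, k]) or i == k:
                continue
            for j in range(n):
                if j == k or j == i or not np.isfinite(D[k, j]):
                    continue
                alt = D[i, k] + D[k, j]
                if alt < D[i, j] - _TIE_TOL * max(1.0, abs(alt)):
                    D[i, j] = alt
                    N[i, j] = N[i, k] * N[k, j]
                elif abs(alt - D[i, j]) <= _TIE_TOL * max(1.0, abs(alt)):
                    # paths whose largest intermediate node is exactly k
                    N[i, j] += N[i, k] * N[k, j]
    return nodes, D, N


def edge_betweenness(
    graph: ResidueGraph | nx.Graph, mode: str = "fractional"
) -> dict[tuple[int, int], float]:
    """Per-edge betweenness from weighted shortest paths.

    ``fractional`` (default): each unordered node pair contributes one
    unit of credit split equally over its co-optimal shortest paths
    (standard Girvan–Newman betweenness).  ``integer``: each co-optimal
    path contributes a full unit, so an edge's credit from a pair is the
    number of shortest paths through it.
    """
    G = graph.graph if isinstance(graph, ResidueGraph) else graph
    if mode == "fractional":
        bc = nx.edge_betweenness_centrality(G, normalized=False, weight="distance")
        return {tuple(sorted(e)): float(v) for e, v in bc.items()}
    if mode != "integer":
        raise ValueError("mode must be 'fractional' or 'integer'")
    rg = graph if isinstance(graph, ResidueGraph) else ResidueGraph(graph=G)
    nodes, D, N = floyd_warshall_paths(rg)
    pos = {v: k for k, v in enumerate(nodes)}
    out: dict[tuple[int, int], float] = {}
    for u, v, data in G.edges(data=True):
        w = float(data["distance"])
        a, b = pos[u], pos[v]
        total = 0.0
        for s in range(len(nodes)):
            for t in range(s + 1, len(nodes)):
                if not np.isfinite(D[s, t]):
                    continue
                for x, y in ((a, b), (b, a)):
                    alt = D[s, x] + w + D[y, t]
                    if abs(alt - D[s, t]) <= _TIE_TOL * max(1.0, abs(alt)):
                        total += N[s, x] * N[y, t]
        out[tuple(sorted((u, v)))] = total
    return out


# --- Girvan–Newman --------------------------------------------------------


def _components_partition(G: nx.Graph) -> list[set[int]]:
    return [set(c) for c in nx.connected_components(G)]


def _modularity(G: nx.Graph, partition: list[set[int]]) -> float:
    if G.number_of_edges() == 0:
        return 0.0
    return float(nx.algorithms.community.modularity(G, partition, weight="correlation"))


def girvan_newman_communities(
    graph: ResidueGraph,
    min_size: int = 3,
    betweenness_mode: str = "fractional",
) -> CommunityPartition:
    """Divisive community decomposition.

    Repeatedly removes the maximum-betweenness edge (ties broken by the
    lexicographically smallest (i, j) pair for determinism), recomputing
    betweenness after every removal, until no edges remain; the partition
    with the highest modularity (scored on the original weighted graph,
    weight = |C|) over the whole trace — including the initial
    connected-components partition — is reported.  Communities smaller
    than ``min_size`` are dropped from the report and returned separately.
    """
    G0 = graph.graph
    if G0.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if G0.number_of_nodes() < min_size:
        raise ValueError(f"graph has fewer than min_size={min_size} nodes")
    work = G0.copy()
    best_partition = _components_partition(work)
    best_q = _modularity(G0, best_partition)
    trace: list[tuple[int, int]] = []
    while work.number_of_edges() > 0:
        bc = edge_betweenness(ResidueGraph(graph=work), mode=betweenness_mode)
        top = max(bc.values())
        candidates = [e for e, v in bc.items() if v >= top - _TIE_TOL * max(1.0, top)]
        edge = min(candidates)
        work.remove_edge(*edge)
        trace.append(edge)
        part = _components_partition(work)
        q = _modularity(G0, part)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = part
    kept = sorted(
        (c for c in best_partition if len(c) >= min_size), key=lambda c: sorted(c)
    )
    discarded = sorted(
        (c for c in best_partition if len(c) < min_size), key=lambda c: sorted(c)
    )
    if discarded:
        warnings.warn(
            f"{len(discarded)} communities below min_size={min_size} discarded",
            stacklevel=2,
        )
    connectivity = community_connectivity(kept, graph)
    return CommunityPartition(
        communities=kept,
        modularity=best_q,
        connectivity=connectivity,
        removal_trace=trace,
        discarded=discarded,
        all_communities=best_partition,
    )


def community_connectivity(
    partition: list[set[int]],
    graph: ResidueGraph,
    betweenness_mode: str = "fractional",
) -> dict[tuple[int, int], float]:
    """Inter-community weights: for communities A, B the weight is the sum
    of original-graph betweenness over edges with one endpoint in each."""
    seen: set[int] = set()
    for comm in partition:
        if seen & comm:
            raise ValueError("overlapping communities")
        seen |= comm
    member: dict[int, int] = {}
    for cid, comm in enumerate(partition):
        for node in comm:
            member[node] = cid
    bc = edge_betweenness(graph, mode=betweenness_mode)
    out: dict[tuple[int, int], float] = {}
    for (u, v), val in bc.items():
        cu, cv = member.get(u), member.get(v)
        if cu is None or cv is None or cu == cv:
            continue
        key = tuple(sorted((cu, cv)))
        out[key] = out.get(key, 0.0) + val
    return out
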
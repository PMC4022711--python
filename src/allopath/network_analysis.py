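"""Dynamic weighted residue-interaction network and community analysis.

The machinery at the heart of the pipeline, following the dynamical-network
approach for MD ensembles:

1. each residue's Cα is a node; an edge joins two residues if they stay in
   contact in a sufficient fraction of frames (the contact map);
2. each edge gets a length w_ij = −log|C_ij| from the motion correlation
   C_ij, so strongly coupled contacts are short — information flows easily;
3. all-pairs shortest paths (Floyd–Warshall) define edge betweenness: the
   number of shortest paths crossing each edge, with co-optimal ties
   contributing fractionally;
4. Girvan–Newman community detection repeatedly removes the highest-
   betweenness edge and keeps the partition of maximal modularity Q, giving
   groups of residues with stronger internal than external coupling;
5. the partition is summarized as a ball-and-stick community graph: ball
   size = residue count, stick value = summed betweenness of the edges
   crossing a community pair — the information flow between communities.

Comparing stick values between two states (apo vs. ligand-bound) exposes
interfaces whose communication is switched on or off by a perturbation.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .correlation import CorrelationMatrix, ResidueLabel
from .errors import CongruenceError, SelectionError
from .structure_io import Ensemble

logger = logging.getLogger(__name__)

Edge = tuple[ResidueLabel, ResidueLabel]

#: Contact criteria (Å): residue-residue minimum heavy-atom distance, with a
#: Cα-Cα fallback for Cα-only (bead / coarse) ensembles.
HEAVY_ATOM_CUTOFF = 4.5
CA_CUTOFF = 8.0
DEFAULT_PERSISTENCE = 0.75
#: Edges with |C_ij| below this are dropped: their −log|C| length diverges.
CORRELATION_FLOOR = 1e-4


def _edge(a: ResidueLabel, b: ResidueLabel) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class ContactGraph:
    """Residue nodes and persistent-contact edges with persistence fractions."""

    nodes: list[ResidueLabel]
    persistence: dict[Edge, float]

    def __post_init__(self) -> None:
        for (a, b), p in self.persistence.items():
            if a == b:
                raise CongruenceError(f"self-edge on node {a}")
            if not 0.0 <= p <= 1.0:
                raise CongruenceError(f"persistence {p} outside [0,1]")


@dataclass
class WeightedNetwork:
    """Contact graph whose edges carry −log|C| lengths and their source C_ij."""

    nodes: list[ResidueLabel]
    edges: dict[Edge, dict]  # each: {"length", "corr", "persistence"}

    def adjacency(self) -> dict[ResidueLabel, dict[ResidueLabel, float]]:
        adj: dict[ResidueLabel, dict[ResidueLabel, float]] = {
            n: {} for n in self.nodes
        }
        for (a, b), attrs in self.edges.items():
            adj[a][b] = attrs["length"]
            adj[b][a] = attrs["length"]
        return adj

    def coupling(self, e: Edge) -> float:
        return abs(self.edges[e]["corr"])


@dataclass
class PathMatrix:
    """All-pairs shortest-path distances and co-optimal path counts."""

    nodes: list[ResidueLabel]
    dist: np.ndarray    # N×N, inf for unreachable
    counts: np.ndarray  # N×N number of co-optimal shortest paths


@dataclass
class BetweennessMap:
    """Per-edge fractional count of all-pairs shortest paths using the edge."""

    values: dict[Edge, float]

    def __post_init__(self) -> None:
        if any(v < -1e-12 for v in self.values.values()):
            raise CongruenceError("betweenness values must be >= 0")


@dataclass
class CommunityPartition:
    """node → community label map with its modularity Q."""

    labels: dict[ResidueLabel, int]
    q: float
    merge_history: list = field(default_factory=list)

    def communities(self) -> dict[int, list[ResidueLabel]]:
        out: dict[int, list[ResidueLabel]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, []).append(node)
        for members in out.values():
            members.sort()
        return out

    def n_communities(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class CommunityGraph:
    """Ball-and-stick summary: ball = community size, stick = summed
    cross-community edge betweenness (the inter-community information flow)."""

    balls: dict[int, int]
    sticks: dict[tuple[int, int], float]


# ---------------------------------------------------------------------------
# Contact map
# ---------------------------------------------------------------------------

def build_contact_graph(ensemble: Ensemble, cutoff: float | None = None,
                        persistence: float = DEFAULT_PERSISTENCE,
                        exclude_neighbors: int = 1) -> ContactGraph:
    """Persistent-contact residue graph of an ensemble.

    A residue pair is in contact in a frame when any heavy-atom pair is
    within ``cutoff`` Å (default 4.5 Å); for Cα-only ensembles the criterion
    falls back to Cα–Cα distance with an 8.0 Å default. The edge is kept
    when the contact holds in at least ``persistence`` of frames and the
    residues are more than ``exclude_neighbors`` apart in sequence.
    """
    if cutoff is not None and cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not 0.0 < persistence <= 1.0:
        raise ValueError("persistence must be in (0, 1]")
    topo = ensemble.topology
    heavy = [i for i, a in enumerate(topo.atoms) if a.element != "H"]
    if not heavy:
        raise SelectionError("ensemble has no heavy atoms")
    ca_only = all(topo.atoms[i].atom_name == "CA" for i in heavy)
    if cutoff is None:
        cutoff = CA_CUTOFF if ca_only else HEAVY_ATOM_CUTOFF

    # group heavy atoms by residue, in residue order of first appearance
    residues: list[ResidueLabel] = []
    atom_groups: dict[ResidueLabel, list[int]] = {}
    for i in heavy:
        a = topo.atoms[i]
        lab = (a.chain_id, a.residue_number)
        if lab not in atom_groups:
            atom_groups[lab] = []
            residues.append(lab)
        atom_groups[lab].append(i)
    residues.sort()
    n = len(residues)
    if n < 2:
        raise SelectionError("need at least two residues for a contact graph")

    counts = np.zeros((n, n))
    if ca_only and all(len(atom_groups[r]) == 1 for r in residues):
        idx = np.array([atom_groups[r][0] for r in residues])
        X = ensemble.coords[:, idx, :]
        # chunk frames to bound the F×N×N distance workspace
        chunk = max(1, int(2e7 // max(n * n, 1)))
        for s in range(0, ensemble.n_frames, chunk):
            block = X[s:s + chunk]
            d2 = np.sum((block[:, :, None, :] - block[:, None, :, :]) ** 2,
                        axis=-1)
            counts += (d2 <= cutoff * cutoff).sum(axis=0)
    else:
        # generic path: per-frame all-atom distances reduced to residue pairs;
        # adequate for probe-sized systems, quadratic in atom count
        flat = [i for r in residues for i in atom_groups[r]]
        owner = np.repeat(np.arange(n), [len(atom_groups[r]) for r in residues])
        for f in range(ensemble.n_frames):
            D = cdist(ensemble.coords[f][flat], ensemble.coords[f][flat])
            hit = D <= cutoff
            # reduce atom-pair hits to residue-pair hits
            res_hit = np.zeros((n, n), dtype=bool)
            ii, jj = np.nonzero(hit)
            res_hit[owner[ii], owner[jj]] = True
            counts += res_hit

    frac = counts / ensemble.n_frames
    edges: dict[Edge, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = residues[i], residues[j]
            if a[0] == b[0] and abs(a[1] - b[1]) <= exclude_neighbors:
                continue
            if frac[i, j] >= persistence:
                edges[_edge(a, b)] = float(frac[i, j])
    return ContactGraph(residues, edges)


# ---------------------------------------------------------------------------
# Edge weighting
# ---------------------------------------------------------------------------

def weight_edges(graph: ContactGraph, dccm: CorrelationMatrix,
                 scheme: str = "log",
                 floor: float = CORRELATION_FLOOR) -> WeightedNetwork:
    """Attach correlation-derived lengths to contact edges.

    ``scheme='log'`` (default) sets w_ij = −log|C_ij| so perfectly
    correlated contacts are at zero network distance; ``scheme='linear'``
    uses 1 − |C_ij|. Edges with |C_ij| below ``floor`` are dropped with a
    warning (their length would diverge).
    """
    index = {lab: k for k, lab in enumerate(dccm.residue_labels)}
    missing = [n for n in graph.nodes if n not in index]
    if missing:
        raise CongruenceError(
            f"correlation matrix lacks residues {missing[:5]}"
        )
    edges: dict[Edge, dict] = {}
    dropped = 0
    for (a, b), pers in graph.persistence.items():
        c = float(dccm.values[index[a], index[b]])
        ac = abs(c)
        if ac < floor:
            dropped += 1
            continue
        if scheme == "log":
            length = -np.log(min(ac, 1.0)) + 0.0  # +0.0 normalizes -0.0
        elif scheme == "linear":
            length = 1.0 - min(ac, 1.0)
        else:
            raise ValueError(f"unknown weighting scheme {scheme!r}")
        edges[_edge(a, b)] = {"length": float(length), "corr": c,
                              "persistence": pers}
    if dropped:
        logger.warning("dropped %d edge(s) with |C| below %.1e", dropped, floor)
    return WeightedNetwork(list(graph.nodes), edges)


# ---------------------------------------------------------------------------
# Shortest paths (Floyd-Warshall with co-optimal path counts)
# ---------------------------------------------------------------------------

_TIE_RTOL = 1e-12


def shortest_paths(network: WeightedNetwork) -> PathMatrix:
    """All-pairs shortest-path distances and co-optimal path counts.

    Floyd-Warshall over the edge lengths; ties within a relative tolerance
    of 1e-12 are treated as co-optimal and their path multiplicities summed.
    Unreachable pairs have infinite distance and zero count.
    """
    nodes = sorted(network.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    cnt = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(cnt, 1.0)
    for (a, b), attrs in network.edges.items():
        i, j = pos[a], pos[b]
        if attrs["length"] < 0:
            raise ValueError("edge lengths must be nonnegative")
        dist[i, j] = dist[j, i] = attrs["length"]
        cnt[i, j] = cnt[j, i] = 1.0
    for k in range(n):
        via = dist[:, k][:, None] + dist[k, :][None, :]
        finite = np.isfinite(dist)
        tol = _TIE_RTOL * (1.0 + np.where(finite, np.abs(dist), 0.0))
        with np.errstate(invalid="ignore"):
            better = via < dist - tol
            equal = np.abs(via - dist) <= tol  # inf-inf -> nan -> False
        # exclude trivial i==k / k==j decompositions from the tie branch
        equal[k, :] = False
        equal[:, k] = False
        np.fill_diagonal(equal, False)
        through = cnt[:, k][:, None] * cnt[k, :][None, :]
        cnt = np.where(better, through, cnt + np.where(equal, through, 0.0))
        dist = np.where(better, via, dist)
    return PathMatrix(nodes, dist, cnt)


# ---------------------------------------------------------------------------
# Edge betweenness (Brandes accumulation on Dijkstra DAGs)
# ---------------------------------------------------------------------------

def _dijkstra(adj: dict, source: ResidueLabel):
    dist: dict[ResidueLabel, float] = {source: 0.0}
    sigma: dict[ResidueLabel, float] = {source: 1.0}
    preds: dict[ResidueLabel, list[ResidueLabel]] = {source: []}
    done: set[ResidueLabel] = set()
    order: list[ResidueLabel] = []
    heap: list[tuple[float, ResidueLabel]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        order.append(u)
        for v, w in adj[u].items():
            nd = d + w
            old = dist.get(v)
            if old is None or nd < old - _TIE_RTOL * (1.0 + abs(old)):
                dist[v] = nd
                sigma[v] = sigma[u]
                preds[v] = [u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - old) <= _TIE_RTOL * (1.0 + abs(old)) and u not in preds[v]:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds, order


def edge_betweenness(network: WeightedNetwork) -> BetweennessMap:
    """Fractional all-pairs shortest-path counts per edge.

    Each unordered node pair contributes 1 split evenly over its co-optimal
    shortest paths; an edge accumulates the share of paths that traverse it
    (Brandes' dependency accumulation, undirected convention).
    """
    adj = network.adjacency()
    bt: dict[Edge, float] = {e: 0.0 for e in network.edges}
    for s in network.nodes:
        _, sigma, preds, order = _dijkstra(adj, s)
        delta: dict[ResidueLabel, float] = {u: 0.0 for u in order}
        for w in reversed(order):
            for v in preds[w]:
                share = sigma[v] / sigma[w] * (1.0 + delta[w])
                bt[_edge(v, w)] += share
                delta[v] += share
    return BetweennessMap({e: v / 2.0 for e, v in bt.items()})


# ---------------------------------------------------------------------------
# Modularity and Girvan-Newman
# ---------------------------------------------------------------------------

def _edge_weight(network: WeightedNetwork, e: Edge, weight: str) -> float:
    if weight == "coupling":
        return abs(network.edges[e]["corr"])
    if weight == "unweighted":
        return 1.0
    raise ValueError(f"unknown modularity weight {weight!r}")


def modularity(network: WeightedNetwork, partition: CommunityPartition | dict,
               weight: str = "coupling") -> float:
    """Newman-Girvan modularity Q = Σ_i (e_ii − a_i²).

    e_ii is the fraction of total edge weight inside community i and a_i the
    fraction of edge ends attached to it. Weight is the coupling strength
    |C_ij| by default (so stronger intraconnections raise Q), or 1 per edge
    with ``weight='unweighted'``.
    """
    labels = partition.labels if isinstance(partition, CommunityPartition) \
        else partition
    missing = [n for n in network.nodes if n not in labels]
    if missing:
        raise CongruenceError(f"partition does not cover nodes {missing[:5]}")
    W = 0.0
    intra: dict = {}
    degree: dict = {}
    for e in network.edges:
        w = _edge_weight(network, e, weight)
        W += w
        a, b = e
        degree[labels[a]] = degree.get(labels[a], 0.0) + w
        degree[labels[b]] = degree.get(labels[b], 0.0) + w
        if labels[a] == labels[b]:
            intra[labels[a]] = intra.get(labels[a], 0.0) + w
    if W == 0.0:
        return 0.0
    q = 0.0
    for c in set(labels.values()):
        e_ii = intra.get(c, 0.0) / W
        a_i = degree.get(c, 0.0) / (2.0 * W)
        q += e_ii - a_i ** 2
    return q


def _components(nodes: list[ResidueLabel],
                adj: dict[ResidueLabel, dict]) -> list[list[ResidueLabel]]:
    seen: set[ResidueLabel] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack = [start]
        comp = []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _partition_from_components(comps: list[list[ResidueLabel]]) -> dict:
    # deterministic community numbering: by smallest member node
    comps = sorted(comps, key=lambda c: c[0])
    return {node: ci for ci, comp in enumerate(comps) for node in comp}


def girvan_newman(network: WeightedNetwork, weight: str = "coupling",
                  removal: str = "betweenness_over_weight"
                  ) -> CommunityPartition:
    """Girvan-Newman community detection at maximal modularity.

    Repeatedly removes the most overloaded edge (recomputing betweenness
    after every removal), scoring the connected-component partition with
    modularity Q on the intact network, and returns the best-Q partition
    seen. With ``removal='betweenness_over_weight'`` (default) the removal
    score is betweenness divided by the coupling strength |C_ij| — Newman's
    weighted-network generalization of the algorithm, in which a weight-w
    edge behaves as w parallel unit edges; this targets weak edges that
    carry disproportionate traffic (community interfaces) rather than the
    strong feeder edges just inside them. ``removal='betweenness'`` is the
    unweighted original. Ties are broken toward the lexicographically
    smallest node pair, so the result is independent of node input order.
    """
    if not network.nodes:
        raise CongruenceError("empty network")
    if removal not in ("betweenness_over_weight", "betweenness"):
        raise ValueError(f"unknown removal rule {removal!r}")
    work = WeightedNetwork(list(network.nodes), dict(network.edges))
    best_q = -np.inf
    best_labels: dict | None = None
    while True:
        comps = _components(sorted(work.nodes), work.adjacency())
        labels = _partition_from_components(comps)
        q = modularity(network, labels, weight=weight)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels
        if not work.edges:
            break
        bt = edge_betweenness(work)
        if removal == "betweenness_over_weight":
            score = {e: v / max(work.coupling(e), 1e-12)
                     for e, v in bt.values.items()}
        else:
            score = bt.values
        top = max(score.values())
        candidates = [e for e, v in score.items() if v >= top - 1e-9 * (1 + top)]
        work.edges.pop(min(candidates))
    assert best_labels is not None
    return CommunityPartition(best_labels, best_q)


def merge_communities(partition: CommunityPartition,
                      network: WeightedNetwork,
                      plan: dict[int, int] | None = None,
                      min_size: int | None = None,
                      weight: str = "coupling") -> CommunityPartition:
    """Coarsen a partition, recomputing Q and recording the merge.

    Either an explicit relabelling ``plan`` (old label → new label) or a
    ``min_size`` rule: communities smaller than ``min_size`` are absorbed,
    smallest first, into the neighbouring community with the strongest
    total inter-community coupling.
    """
    labels = dict(partition.labels)
    history = list(partition.merge_history)
    if plan is not None:
        known = set(labels.values())
        bad = [old for old in plan if old not in known]
        if bad:
            raise CongruenceError(f"merge plan references unknown labels {bad}")
        bad = [new for new in plan.values()
               if new not in known and new not in plan]
        if bad:
            raise CongruenceError(f"merge plan maps to nonexistent labels {bad}")
        labels = {n: plan.get(c, c) for n, c in labels.items()}
        history.append({"plan": dict(plan)})
    elif min_size is not None:
        while True:
            sizes: dict[int, int] = {}
            for c in labels.values():
                sizes[c] = sizes.get(c, 0) + 1
            small = sorted(c for c, s in sizes.items() if s < min_size)
            if not small or len(sizes) == 1:
                break
            c0 = min(small, key=lambda c: (sizes[c], c))
            # strongest-coupled neighbouring community
            strength: dict[int, float] = {}
            for (a, b) in network.edges:
                ca, cb = labels.get(a), labels.get(b)
                if ca == c0 and cb != c0:
                    strength[cb] = strength.get(cb, 0.0) + \
                        _edge_weight(network, (a, b), weight)
                elif cb == c0 and ca != c0:
                    strength[ca] = strength.get(ca, 0.0) + \
                        _edge_weight(network, (a, b), weight)
            if not strength:
                break  # isolated small community: nothing to absorb it
            target = max(sorted(strength), key=lambda c: strength[c])
            labels = {n: (target if c == c0 else c) for n, c in labels.items()}
            history.append({"absorbed": c0, "into": target})
    else:
        raise ValueError("provide either a merge plan or min_size")
    q = modularity(network, labels, weight=weight)
    return CommunityPartition(labels, q, history)


# ---------------------------------------------------------------------------
# Ball-and-stick community graphs
# ---------------------------------------------------------------------------

def community_graph(network: WeightedNetwork, partition: CommunityPartition,
                    betweenness: BetweennessMap,
                    exclude_nodes: set[ResidueLabel] | None = None
                    ) -> CommunityGraph:
    """Coarse ball-and-stick summary of a partitioned network.

    Ball size is the residue count of each community; stick value the sum
    of edge betweenness over edges crossing that community pair. Nodes in
    ``exclude_nodes`` (e.g. a flexible terminus far from the region of
    interest) are discarded first.
    """
    exclude = exclude_nodes or set()
    labels = {n: c for n, c in partition.labels.items() if n not in exclude}
    balls: dict[int, int] = {}
    for c in labels.values():
        balls[c] = balls.get(c, 0) + 1
    sticks: dict[tuple[int, int], float] = {}
    for e, bt in betweenness.values.items():
        a, b = e
        if a in exclude or b in exclude:
            continue
        ca, cb = labels[a], labels[b]
        if ca == cb:
            continue
        key = (ca, cb) if ca <= cb else (cb, ca)
        sticks[key] = sticks.get(key, 0.0) + bt
    return CommunityGraph(balls, sticks)


def compare_networks(a: CommunityGraph, b: CommunityGraph,
                     label_map: dict[int, int] | None = None
                     ) -> list[tuple[tuple[int, int], float]]:
    """Signed stick differences (state b − state a), sorted by magnitude.

    ``label_map`` translates state-b community labels into state-a labels
    (identity if omitted); every community of b must be mapped or shared.
    """
    label_map = label_map or {}
    def remap(c: int) -> int:
        if c in label_map:
            return label_map[c]
        if c in a.balls:
            return c
        raise CongruenceError(f"community {c} of state b has no counterpart")
    b_sticks: dict[tuple[int, int], float] = {}
    for (p, q), v in b.sticks.items():
        rp, rq = remap(p), remap(q)
        key = (rp, rq) if rp <= rq else (rq, rp)
        b_sticks[key] = b_sticks.get(key, 0.0) + v
    pairs = set(a.sticks) | set(b_sticks)
    diffs = [(pair, b_sticks.get(pair, 0.0) - a.sticks.get(pair, 0.0))
             for pair in pairs]
    diffs.sort(key=lambda t: (-abs(t[1]), t[0]))
    return diffs
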
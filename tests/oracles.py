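"""Independent reference implementations used only to check the package.

Each oracle is deliberately written with a different algorithm than the
implementation it checks: quaternion eigenproblem vs. SVD Kabsch, naive
double loops vs. vectorized einsum, array Dijkstra vs. Floyd-Warshall,
exhaustive path/partition enumeration vs. Brandes/Girvan-Newman.
"""

from __future__ import annotations

import itertools

import numpy as np


# --- superposition: Horn's quaternion method -------------------------------

def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the quaternion 4x4 eigenproblem."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = P.shape[0]
    msd = max(((P ** 2).sum() + (Q ** 2).sum() - 2.0 * lam_max) / n, 0.0)
    return float(np.sqrt(msd))


# --- PCA: singular value decomposition -------------------------------------

def pca_svd(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenpairs of the 1/F covariance of row-observations X via SVD.

    Returns (mean, eigenvalues desc, eigenvector columns)."""
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s ** 2 / X.shape[0]
    return mean, lam, Vt.T


# --- DCCM: naive double loop ------------------------------------------------

def dccm_double_loop(disp: np.ndarray) -> np.ndarray:
    """DCCM from F×N×3 displacement vectors, one pair at a time."""
    F, N, _ = disp.shape
    C = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            num = sum(float(disp[f, i] @ disp[f, j]) for f in range(F)) / F
            vi = sum(float(disp[f, i] @ disp[f, i]) for f in range(F)) / F
            vj = sum(float(disp[f, j] @ disp[f, j]) for f in range(F)) / F
            C[i, j] = num / np.sqrt(vi * vj)
    return C


# --- shortest paths: O(V^2) array Dijkstra ----------------------------------

def dijkstra_distances(nodes: list, edges: dict) -> dict:
    """All-pairs distances via per-source array Dijkstra (no heap).

    ``edges`` maps unordered (u, v) tuples to nonnegative lengths.
    """
    adj: dict = {n: {} for n in nodes}
    for (u, v), w in edges.items():
        adj[u][v] = w
        adj[v][u] = w
    out = {}
    for s in nodes:
        dist = {n: np.inf for n in nodes}
        dist[s] = 0.0
        todo = set(nodes)
        while todo:
            u = min(todo, key=lambda n: dist[n])
            todo.discard(u)
            if dist[u] == np.inf:
                break
            for v, w in adj[u].items():
                if dist[u] + w < dist[v]:
                    dist[v] = dist[u] + w
        for t in nodes:
            out[(s, t)] = dist[t]
    return out


# --- betweenness: exhaustive co-optimal path enumeration --------------------

def _all_simple_paths(adj: dict, s, t, rtol=1e-12):
    """All simple paths s->t as (length, edge list)."""
    paths = []

    def walk(u, seen, length, used):
        if u == t:
            paths.append((length, list(used)))
            return
        for v, w in adj[u].items():
            if v not in seen:
                seen.add(v)
                used.append((u, v) if u <= v else (v, u))
                walk(v, seen, length + w, used)
                used.pop()
                seen.discard(v)

    walk(s, {s}, 0.0, [])
    return paths


def brute_edge_betweenness(nodes: list, edges: dict) -> dict:
    """Fractional edge betweenness by enumerating every simple path of every
    unordered node pair and keeping the co-optimal ones."""
    adj: dict = {n: {} for n in nodes}
    for (u, v), w in edges.items():
        adj[u][v] = w
        adj[v][u] = w
    bt = {e: 0.0 for e in edges}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        best = min(p[0] for p in paths)
        optimal = [p for p in paths if p[0] <= best + 1e-12 * (1.0 + best)]
        share = 1.0 / len(optimal)
        for _, used in optimal:
            for e in used:
                bt[e] += share
    return bt


def brute_path_counts(nodes: list, edges: dict) -> dict:
    """Number of co-optimal shortest paths per unordered node pair."""
    adj: dict = {n: {} for n in nodes}
    for (u, v), w in edges.items():
        adj[u][v] = w
        adj[v][u] = w
    out = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            out[(s, t)] = (np.inf, 0)
            continue
        best = min(p[0] for p in paths)
        k = sum(1 for p in paths if p[0] <= best + 1e-12 * (1.0 + best))
        out[(s, t)] = (best, k)
    return out


# --- modularity: exhaustive search over all set partitions ------------------

def _set_partitions(items: list):
    """Every partition of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def exhaustive_max_modularity(nodes: list, weighted_edges: dict
                              ) -> tuple[float, list[list]]:
    """Globally best-Q partition by brute force (feasible to ~8 nodes).

    ``weighted_edges`` maps unordered node pairs to the modularity weight
    (coupling strength)."""
    W = sum(weighted_edges.values())
    best_q, best_p = -np.inf, None
    for parts in _set_partitions(list(nodes)):
        label = {n: i for i, grp in enumerate(parts) for n in grp}
        intra: dict[int, float] = {}
        deg: dict[int, float] = {}
        for (u, v), w in weighted_edges.items():
            deg[label[u]] = deg.get(label[u], 0.0) + w
            deg[label[v]] = deg.get(label[v], 0.0) + w
            if label[u] == label[v]:
                intra[label[u]] = intra.get(label[u], 0.0) + w
        q = sum(intra.get(c, 0.0) / W - (deg.get(c, 0.0) / (2 * W)) ** 2
                for c in range(len(parts)))
        if q > best_q + 1e-12:
            best_q, best_p = q, parts
    return best_q, best_p


# --- statistics: streaming two-pass -----------------------------------------

def two_pass_stats(values: np.ndarray) -> tuple[float, float]:
    """Population mean and s.d. via an explicit two-pass accumulation."""
    n = len(values)
    mean = sum(float(v) for v in values) / n
    var = sum((float(v) - mean) ** 2 for v in values) / n
    return mean, float(np.sqrt(var))


# --- partition agreement -----------------------------------------------------

def adjusted_rand_index(a: list, b: list) -> float:
    """Chance-corrected agreement between two labelings."""
    from collections import Counter

    n = len(a)
    comb = lambda x: x * (x - 1) / 2.0
    nij = Counter(zip(a, b))
    ai = Counter(a)
    bj = Counter(b)
    s = sum(comb(v) for v in nij.values())
    sa = sum(comb(v) for v in ai.values())
    sb = sum(comb(v) for v in bj.values())
    expected = sa * sb / comb(n)
    maximum = (sa + sb) / 2.0
    if maximum == expected:
        return 1.0
    return (s - expected) / (maximum - expected)
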
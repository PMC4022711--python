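from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import allopath as ap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


MINIMAL_PDB = """\
ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.800   2.000   3.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bead_model(coords, chain="A"):
    """Cα bead StructureModel from an N×3 array."""
    coords = np.asarray(coords, dtype=float)
    atoms = [
        ap.Atom(i + 1, "CA", "GLY", chain, i + 1, "C", coords[i].copy())
        for i in range(coords.shape[0])
    ]
    return ap.StructureModel(atoms)


def bead_ensemble(frames, chain="A", dt=1.0):
    """Ensemble from an F×N×3 array of Cα coordinates."""
    frames = np.asarray(frames, dtype=float)
    topo = bead_model(frames[0], chain)
    times = np.arange(frames.shape[0], dtype=float) * dt
    return ap.Ensemble(topo, frames, times)


def toy_network(edge_corr):
    """WeightedNetwork over integer-labelled bead nodes.

    ``edge_corr`` maps (i, j) residue-number pairs to correlation values;
    nodes are ('A', i)."""
    nodes = sorted({n for e in edge_corr for n in e})
    labels = [("A", n) for n in nodes]
    edges = {}
    for (i, j), c in edge_corr.items():
        a, b = ("A", i), ("A", j)
        e = (a, b) if a <= b else (b, a)
        edges[e] = {"length": float(-np.log(abs(c))), "corr": float(c),
                    "persistence": 1.0}
    return ap.WeightedNetwork(labels, edges)


def random_weighted_network(rng, n, p=0.4, ensure_connected=True):
    """Random correlation-weighted network for oracle comparisons."""
    while True:
        corr = {}
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if rng.random() < p:
                    corr[(i, j)] = float(rng.uniform(0.05, 0.95))
        if not corr:
            continue
        net = toy_network(corr)
        if not ensure_connected:
            return net
        # connectivity check via union of adjacency
        adj = net.adjacency()
        seen = set()
        stack = [net.nodes[0]]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u])
        if len(seen) == len(net.nodes):
            return net
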
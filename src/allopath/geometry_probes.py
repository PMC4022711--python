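"""Residue-level geometric probes over an ensemble.

Distance series between atoms or atom groups, hydrogen-bond occupancy under
a distance(+angle) criterion, and torsion-angle series (e.g. the side-chain
χ2 of a tryptophan, whose ~180° change signals an indole ring flip). All
measures are internal distances/angles and therefore invariant under rigid
motion of the frames — no superposition is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SelectionError
from .structure_io import Ensemble, Selection, StructureModel

#: Default H-bond criterion: donor-acceptor heavy-atom distance and, when a
#: hydrogen is available, the D-H···A angle. Common MD-analysis practice;
#: occupancies depend on these and both are caller-adjustable.
HBOND_DISTANCE_CUTOFF = 3.5
HBOND_ANGLE_CUTOFF = 135.0

AtomSpec = tuple  # (chain_id | None, residue_number, atom_name)


@dataclass
class DistanceSeries:
    """Per-frame distance (Å) with frame times (ps) and a label."""

    times: np.ndarray
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(self.values < 0):
            raise ValueError("distances must be >= 0")


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    ``donor``/``acceptor`` are heavy-atom specs; ``hydrogen`` is optional —
    without it only the distance gate applies. Ambiguous carboxylate-style
    names (e.g. ``"OE"`` for a glutamate) match all atoms with that prefix
    and the closest one counts.
    """

    donor: AtomSpec
    acceptor: AtomSpec
    hydrogen: AtomSpec | None = None
    d_cutoff: float = HBOND_DISTANCE_CUTOFF
    angle_cutoff: float = HBOND_ANGLE_CUTOFF

    def __post_init__(self) -> None:
        if self.d_cutoff <= 0:
            raise ValueError("d_cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle_cutoff must be in (0, 180]")


def _resolve(topo: StructureModel, spec: AtomSpec,
             allow_ambiguous: bool = False) -> list[int]:
    """Atom indices matching (chain, resnum, name); prefix match as fallback."""
    chain, resnum, name = spec
    exact = [i for i, a in enumerate(topo.atoms)
             if (chain is None or a.chain_id == chain)
             and a.residue_number == resnum and a.atom_name == name]
    if exact:
        return exact
    if allow_ambiguous:
        prefix = [i for i, a in enumerate(topo.atoms)
                  if (chain is None or a.chain_id == chain)
                  and a.residue_number == resnum
                  and a.atom_name.startswith(name)]
        if prefix:
            return prefix
    raise SelectionError(f"atom {name} of residue {resnum} not found")


def distance_series(ensemble: Ensemble, a: AtomSpec, b: AtomSpec,
                    label: str | None = None) -> DistanceSeries:
    """Euclidean distance between two named atoms, per frame."""
    ia = _resolve(ensemble.topology, a)[0]
    ib = _resolve(ensemble.topology, b)[0]
    d = np.linalg.norm(ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :],
                       axis=1)
    label = label or f"{a[2]}{a[1]}-{b[2]}{b[1]}"
    return DistanceSeries(ensemble.times.copy(), d, label)


def group_distance_series(ensemble: Ensemble, sel_a: Selection,
                          sel_b: Selection, mode: str = "min",
                          label: str = "group") -> DistanceSeries:
    """Per-frame distance between two atom groups.

    ``mode='min'``: minimum pairwise distance (side-chain contact distance);
    ``mode='centroid'``: distance between geometric centres.
    """
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise SelectionError("group selections must be non-empty")
    A = ensemble.coords[:, sel_a.indices, :]
    B = ensemble.coords[:, sel_b.indices, :]
    if mode == "min":
        diff = A[:, :, None, :] - B[:, None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))
    elif mode == "centroid":
        d = np.linalg.norm(A.mean(axis=1) - B.mean(axis=1), axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceSeries(ensemble.times.copy(), d, label)


def hbond_occupancy(ensemble: Ensemble, criterion: HBondCriterion
                    ) -> tuple[float, np.ndarray]:
    """Fraction of frames satisfying the H-bond criterion, plus the per-frame
    boolean series.

    Distance gate: min donor–acceptor heavy-atom distance ≤ d_cutoff (over
    ambiguous name matches). Angle gate (only when a hydrogen is given):
    D-H···A angle ≥ angle_cutoff, evaluated for the acceptor atom closest
    in that frame.
    """
    topo = ensemble.topology
    don = _resolve(topo, criterion.donor, allow_ambiguous=True)
    acc = _resolve(topo, criterion.acceptor, allow_ambiguous=True)
    D = ensemble.coords[:, don, :]
    A = ensemble.coords[:, acc, :]
    diff = D[:, :, None, :] - A[:, None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))        # F × |don| × |acc|
    flat = dist.reshape(ensemble.n_frames, -1)
    ok = flat.min(axis=1) <= criterion.d_cutoff
    if criterion.hydrogen is not None:
        ih = _resolve(topo, criterion.hydrogen, allow_ambiguous=True)[0]
        H = ensemble.coords[:, ih, :]
        best = flat.argmin(axis=1)
        bi, bj = np.unravel_index(best, dist.shape[1:])
        Dbest = D[np.arange(ensemble.n_frames), bi]
        Abest = A[np.arange(ensemble.n_frames), bj]
        v1 = Dbest - H
        v2 = Abest - H
        cosang = (v1 * v2).sum(axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok &= angle >= criterion.angle_cutoff
    return float(ok.mean()), ok


def dihedral_series(ensemble: Ensemble, a: AtomSpec, b: AtomSpec,
                    c: AtomSpec, d: AtomSpec) -> np.ndarray:
    """Signed torsion angle a-b-c-d per frame, degrees in (−180, 180].

    Uses the standard atan2 construction. A collinear consecutive triple
    makes the torsion undefined for that frame and raises an error.
    """
    idx = [_resolve(ensemble.topology, s)[0] for s in (a, b, c, d)]
    P = ensemble.coords[:, idx, :]
    b1 = P[:, 1] - P[:, 0]
    b2 = P[:, 2] - P[:, 1]
    b3 = P[:, 3] - P[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=1) < 1e-10) or \
            np.any(np.linalg.norm(n2, axis=1) < 1e-10):
        raise ValueError("collinear atom triple: torsion undefined")
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = (n1 * n2).sum(axis=1)
    y = (np.cross(n1, n2) * b2n).sum(axis=1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    ang[np.isclose(ang, -180.0)] = 180.0
    return ang


def series_stats(series: DistanceSeries) -> dict[str, float]:
    """Population mean, s.d., min and max of a series."""
    v = series.values
    if v.size == 0:
        raise ValueError("empty series")
    return {
        "mean": float(v.mean()),
        "sd": float(v.std()),
        "min": float(v.min()),
        "max": float(v.max()),
    }
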
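"""Dynamic cross-correlation matrices (DCCM) and state-difference maps.

The DCCM entry for residues i, j is the normalized covariance of their
3-D Cα displacement vectors over the analyzed frames:

    C_ij = <Δr_i · Δr_j> / sqrt(<Δr_i²> <Δr_j²>)

with Δr the displacement from the mean position after rigid-body alignment.
C_ij = +1 means fully correlated motion (same direction), −1 fully
anti-correlated, ~0 independent. Differencing the matrices of two states
(e.g. ligand-bound minus apo) highlights couplings created or destroyed by
a perturbation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import CongruenceError
from .structure_io import (
    Ensemble,
    Selection,
    StructureModel,
    align_ensemble,
    ca_selection,
)

logger = logging.getLogger(__name__)

ResidueLabel = tuple[str, int]  # (chain_id, residue_number)


@dataclass
class CorrelationMatrix:
    """N×N residue-residue correlation with its residue labels."""

    values: np.ndarray
    residue_labels: list[ResidueLabel]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_labels)
        if self.values.shape != (n, n):
            raise CongruenceError(
                f"matrix {self.values.shape} vs {n} residue labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise CongruenceError("correlation matrix must be symmetric")
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise CongruenceError("correlation entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.residue_labels)

    def entry(self, a: ResidueLabel, b: ResidueLabel) -> float:
        i = self.residue_labels.index(a)
        j = self.residue_labels.index(b)
        return float(self.values[i, j])


def compute_dccm(ensemble: Ensemble, sel: Selection | None = None,
                 reference: StructureModel | None = None,
                 fit: Selection | None = None) -> CorrelationMatrix:
    """DCCM of the Cα displacement vectors of ``sel`` atoms.

    If ``reference`` is given, every frame is first superposed onto it
    (fit: all Cα by default) to remove rigid-body motion, as required for
    real trajectories. ``reference=None`` skips alignment — appropriate for
    ensembles generated directly in a common frame, where superposition
    would itself remove part of the planted collective motion.

    Zero-variance residues get 0 off-diagonal (diagonal 1 by convention)
    with a warning.
    """
    if ensemble.n_frames < 2:
        raise CongruenceError("DCCM needs at least 2 frames")
    if sel is None:
        sel = ca_selection(ensemble.topology)
    if reference is not None:
        ensemble = align_ensemble(ensemble, reference, fit)
    X = ensemble.coords[:, sel.indices, :]          # F × N × 3
    D = X - X.mean(axis=0, keepdims=True)
    # covariance of 3-D displacement vectors: time-average of dot products
    cov = np.einsum("fic,fjc->ij", D, D) / ensemble.n_frames
    var = np.diag(cov).copy()
    dead = var <= 0.0
    if dead.any():
        logger.warning("%d zero-variance residue(s) in DCCM; rows zeroed",
                       int(dead.sum()))
    denom = np.sqrt(np.where(dead, 1.0, var))
    C = cov / denom[:, None] / denom[None, :]
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    C = 0.5 * (C + C.T)
    labels = [
        (ensemble.topology.atoms[i].chain_id,
         ensemble.topology.atoms[i].residue_number)
        for i in sel.indices
    ]
    return CorrelationMatrix(C, labels)


def differential_dccm(state_b: CorrelationMatrix,
                      state_a: CorrelationMatrix) -> np.ndarray:
    """Elementwise B − A difference map (entries in [−2, 2]).

    Residue labels must match exactly; no silent reindexing.
    """
    if state_b.residue_labels != state_a.residue_labels:
        raise CongruenceError("residue labels differ between the two matrices")
    return state_b.values - state_a.values


def block_summary(diff: np.ndarray, partition: dict[ResidueLabel, object],
                  residue_labels: list[ResidueLabel]) -> dict[tuple, float]:
    """Mean |ΔC| per community pair.

    ``partition`` maps every residue label of ``diff`` to a community label.
    Returns a symmetric table keyed by unordered community pairs (p, q) with
    p <= q by string order; diagonal pairs (p, p) exclude the self-diagonal
    of the matrix.
    """
    n = len(residue_labels)
    if np.shape(diff) != (n, n):
        raise CongruenceError("difference matrix does not match residue labels")
    missing = [lab for lab in residue_labels if lab not in partition]
    if missing:
        raise CongruenceError(f"partition does not cover residues {missing[:5]}")
    comm = [partition[lab] for lab in residue_labels]
    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((comm[i], comm[j]), key=str))
            sums[key] = sums.get(key, 0.0) + abs(diff[i, j])
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}
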
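"""Essential dynamics: positional covariance PCA of an aligned ensemble.

The covariance matrix C of the Cartesian coordinates of a selected atom
subset (typically Cα atoms of a loop or domain) is built after removing
rigid-body motion by superposing every frame onto a reference structure.
Its eigenvectors are the principal components — independent collective
modes of motion — and the eigenvalues their mean-square amplitudes in Ų.
Projections of individual frames onto the leading components locate each
conformation along those modes.

Normalisation is 1/F (a time average over frames), so eigenvalues are
mean-square, not unbiased-sample, amplitudes. The centring origin is the
post-alignment ensemble mean; the reference only fixes the frame of
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CongruenceError
from .structure_io import (
    Ensemble,
    Selection,
    StructureModel,
    align_ensemble,
    ca_selection,
    kabsch_superpose,
)


@dataclass
class PCModel:
    """Result of a positional-covariance PCA.

    ``mean_coords`` (3N, Å) and ``covariance`` (3N×3N, Ų) are over the
    analysis selection; ``eigenvalues`` are sorted descending and
    ``eigenvectors[:, i]`` is the i-th orthonormal principal component.
    ``fit_selection``/``reference_coords`` record the superposition used, so
    new frames can be projected consistently.
    """

    mean_coords: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    selection: Selection
    fit_selection: Selection
    reference_coords: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry positive."""
    out = vecs.copy()
    for i in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, i])))
        if out[j, i] < 0:
            out[:, i] = -out[:, i]
    return out


def fit_pca(ensemble: Ensemble, sel: Selection, reference: StructureModel,
            fit: Selection | None = None, align: bool = True) -> PCModel:
    """Diagonalize the positional covariance of ``sel`` atoms.

    Frames are first superposed onto ``reference`` using the ``fit``
    selection (default: all Cα atoms). Set ``align=False`` for ensembles
    already expressed in a common frame (e.g. synthetic ones).
    """
    if ensemble.n_frames < 2:
        raise CongruenceError("PCA needs at least 2 frames")
    if len(sel) == 0:
        raise CongruenceError("empty analysis selection")
    if fit is None:
        fit = ca_selection(ensemble.topology)
    if align:
        ensemble = align_ensemble(ensemble, reference, fit)
    X = ensemble.coords[:, sel.indices, :].reshape(ensemble.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / ensemble.n_frames
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = _fix_signs(V[:, order])
    return PCModel(
        mean_coords=mean,
        covariance=cov,
        eigenvalues=w,
        eigenvectors=V,
        selection=sel,
        fit_selection=fit,
        reference_coords=reference.coords,
    )


def project(model: PCModel, frame: np.ndarray, i: int,
            align: bool = True) -> float:
    """Projection of one frame (A×3, full topology) onto the i-th PC, in Å.

    The frame is superposed onto the stored reference with the stored fit
    selection before the dot product V_i · (x − <x>).
    """
    if not 0 <= i < model.n_components:
        raise IndexError(f"PC index {i} out of range (have {model.n_components})")
    frame = np.asarray(frame, dtype=float)
    if frame.shape != model.reference_coords.shape:
        raise CongruenceError(
            f"frame shape {frame.shape} does not match topology "
            f"{model.reference_coords.shape}"
        )
    if align:
        frame, _, _, _ = kabsch_superpose(frame, model.reference_coords,
                                          model.fit_selection)
    x = frame[model.selection.indices].reshape(-1)
    return float(model.eigenvectors[:, i] @ (x - model.mean_coords))


def project_ensemble(model: PCModel, ensemble: Ensemble, n_pcs: int = 2,
                     align: bool = True) -> np.ndarray:
    """F×n_pcs matrix of projections (the PC1/PC2 scatter of each frame)."""
    if n_pcs > model.n_components:
        raise IndexError(f"n_pcs={n_pcs} exceeds {model.n_components} components")
    out = np.empty((ensemble.n_frames, n_pcs))
    V = model.eigenvectors[:, :n_pcs]
    for f in range(ensemble.n_frames):
        frame = ensemble.coords[f]
        if align:
            frame, _, _, _ = kabsch_superpose(frame, model.reference_coords,
                                              model.fit_selection)
        x = frame[model.selection.indices].reshape(-1)
        out[f] = (x - model.mean_coords) @ V
    return out


def variance_profile(model: PCModel, k: int) -> np.ndarray:
    """Cumulative variance fractions of the first k components."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > model.n_components:
        raise ValueError(f"k={k} exceeds number of components {model.n_components}")
    lam = np.clip(model.eigenvalues, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("covariance has zero total variance")
    return np.cumsum(lam[:k]) / total
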
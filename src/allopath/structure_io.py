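"""Structures, ensembles, selections, superposition and RMSD.

This module is the geometric substrate of the pipeline: it reads single- and
multi-model PDB files (one frame per MODEL record) into lightweight numpy
containers, selects atom subsets with a small expression language, removes
rigid-body motion by least-squares (Kabsch) superposition and computes RMSD
time series.

Conventions: coordinates in Å, times in ps, residue numbers 1-based as in
the PDB file, internal atom indices 0-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import gemmi
import numpy as np

from .errors import (
    CongruenceError,
    DegenerateFitError,
    ParseError,
    SelectionError,
)

logger = logging.getLogger(__name__)

#: Backbone atom names; everything else in a residue counts as side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class Atom:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    position: np.ndarray  # shape (3,), Å


@dataclass
class StructureModel:
    """A single conformation: atom metadata plus Å coordinates.

    Invariants: all (chain_id, residue_number, atom_name) triples are unique
    and all positions are finite; both are enforced at construction.
    """

    atoms: list[Atom]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in seen:
                raise ParseError(
                    f"duplicate atom {a.atom_name} in {a.chain_id}/{a.residue_number}"
                )
            seen.add(key)
        if self.atoms and not np.all(np.isfinite(self.coords)):
            raise ParseError("non-finite coordinates in structure")

    @property
    def coords(self) -> np.ndarray:
        """A×3 coordinate array (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_keys(self) -> list[tuple[str, int, str]]:
        return [(a.chain_id, a.residue_number, a.atom_name) for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise CongruenceError(
                f"coordinate array {coords.shape} does not match {self.n_atoms} atoms"
            )
        atoms = [
            Atom(a.serial, a.atom_name, a.residue_name, a.chain_id,
                 a.residue_number, a.element, coords[i].copy())
            for i, a in enumerate(self.atoms)
        ]
        return StructureModel(atoms)

    def index_of(self, chain_id: str | None, residue_number: int, atom_name: str) -> int:
        """0-based index of a named atom; chain None matches any chain."""
        for i, a in enumerate(self.atoms):
            if (chain_id is None or a.chain_id == chain_id) and \
                    a.residue_number == residue_number and a.atom_name == atom_name:
                return i
        raise SelectionError(
            f"atom {atom_name} of residue {residue_number}"
            f"{'' if chain_id is None else ' chain ' + chain_id} not found"
        )


@dataclass
class Ensemble:
    """F frames × A atoms × 3 Å coordinates with strictly increasing times (ps)."""

    topology: StructureModel
    coords: np.ndarray          # (F, A, 3)
    times: np.ndarray           # (F,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise CongruenceError(f"coords must be F×A×3, got {self.coords.shape}")
        F, A, _ = self.coords.shape
        if F < 1 or A < 1:
            raise CongruenceError("ensemble needs at least one frame and one atom")
        if A != self.topology.n_atoms:
            raise CongruenceError(
                f"{A} coordinate columns vs {self.topology.n_atoms} topology atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise CongruenceError("non-finite coordinates in ensemble")
        if len(self.times) != F:
            raise CongruenceError("times length must equal frame count")
        if F > 1 and not np.all(np.diff(self.times) > 0):
            raise CongruenceError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i])


@dataclass(frozen=True)
class Selection:
    """Ordered, unique 0-based atom indices into a topology."""

    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise SelectionError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _model_to_structure(model: gemmi.Model, chain_id: str | None) -> StructureModel:
    atoms: list[Atom] = []
    for chain in model:
        if chain_id is not None and chain.name != chain_id:
            continue
        for res in chain:
            for atom in res:
                # keep altloc blank or 'A'; drop alternates
                if atom.altloc not in ("", "\0", "A"):
                    logger.debug("dropping altloc %r of %s/%d/%s",
                                 atom.altloc, chain.name, res.seqid.num, atom.name)
                    continue
                atoms.append(Atom(
                    serial=atom.serial,
                    atom_name=atom.name,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                ))
    return StructureModel(atoms)


def read_structure(path: str, model_index: int = 0,
                   chain_id: str | None = None) -> StructureModel:
    """Read one MODEL of a (possibly multi-model) PDB file.

    ``model_index`` is 0-based over the MODEL records in file order;
    ``chain_id`` restricts to one chain (default: all chains).
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi reports line info itself
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in {path}")
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range: {path} has {len(st)} model(s)"
        )
    model = _model_to_structure(st[model_index], chain_id)
    if model.n_atoms == 0:
        raise ParseError(f"model {model_index} of {path} contains no atoms")
    return model


def read_ensemble(path: str, dt: float = 1.0,
                  chain_id: str | None = None) -> Ensemble:
    """Read a multi-model PDB as an ensemble (one frame per MODEL).

    All models must contain the same atoms in the same order. Frame times
    default to ``frame_index * dt`` ps.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in {path}")
    frames = [_model_to_structure(m, chain_id) for m in st]
    topo = frames[0]
    keys = topo.atom_keys()
    for i, f in enumerate(frames[1:], start=1):
        if f.atom_keys() != keys:
            raise CongruenceError(
                f"model {i} of {path} has a different atom set than model 0"
            )
    coords = np.stack([f.coords for f in frames])
    times = np.arange(len(frames), dtype=float) * dt
    return Ensemble(topo, coords, times)


def write_ensemble(path: str, ensemble: Ensemble) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks)."""
    st = gemmi.Structure()
    # gemmi's add_* methods copy their argument, so build bottom-up:
    # atoms into residues, residues into chains, chains into the model.
    for fi in range(ensemble.n_frames):
        model = gemmi.Model(fi + 1)
        chain_order: list[str] = []
        per_chain: dict[str, list[tuple[tuple[int, str], list[int]]]] = {}
        for ai, a in enumerate(ensemble.topology.atoms):
            if a.chain_id not in per_chain:
                per_chain[a.chain_id] = []
                chain_order.append(a.chain_id)
            groups = per_chain[a.chain_id]
            rkey = (a.residue_number, a.residue_name)
            if not groups or groups[-1][0] != rkey:
                groups.append((rkey, []))
            groups[-1][1].append(ai)
        for cid in chain_order:
            chain = gemmi.Chain(cid)
            for (resnum, resname), atom_ids in per_chain[cid]:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                for ai in atom_ids:
                    a = ensemble.topology.atoms[ai]
                    atom = gemmi.Atom()
                    atom.name = a.atom_name
                    atom.element = gemmi.Element(a.element if a.element else "X")
                    atom.serial = a.serial
                    x, y, z = ensemble.coords[fi, ai]
                    atom.pos = gemmi.Position(float(x), float(y), float(z))
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_structure(path: str, model: StructureModel) -> None:
    """Write a single-model PDB."""
    ens = Ensemble(model, model.coords[None, :, :], np.array([0.0]))
    write_ensemble(path, ens)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")


def _parse_clause(clause: str, topo: StructureModel) -> set[int]:
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty selection clause")
    kw = tokens[0].lower()
    args = " ".join(tokens[1:])
    idx = range(topo.n_atoms)
    if kw == "name":
        names = {n.strip() for n in args.replace(",", " ").split()}
        if not names:
            raise SelectionError("'name' needs at least one atom name")
        return {i for i in idx if topo.atoms[i].atom_name in names}
    if kw in ("resid", "residue", "resnum"):
        wanted: set[int] = set()
        for part in args.replace(",", " ").split():
            m = _RANGE_RE.match(part)
            if m:
                wanted.update(range(int(m.group(1)), int(m.group(2)) + 1))
            elif part.isdigit():
                wanted.add(int(part))
            else:
                raise SelectionError(f"bad residue specifier {part!r}")
        if not wanted:
            raise SelectionError("'resid' needs residue numbers")
        return {i for i in idx if topo.atoms[i].residue_number in wanted}
    if kw == "chain":
        chains = set(args.replace(",", " ").split())
        return {i for i in idx if topo.atoms[i].chain_id in chains}
    if kw == "sidechain" and not args:
        return {i for i in idx if topo.atoms[i].atom_name not in BACKBONE_ATOMS
                and topo.atoms[i].element != "H"}
    if kw == "heavy" and not args:
        return {i for i in idx if topo.atoms[i].element != "H"}
    if kw == "all" and not args:
        return set(idx)
    raise SelectionError(f"cannot parse selection clause {clause!r}")


def select(topology: StructureModel, spec: str) -> Selection:
    """Select atoms with a small expression language.

    Clauses joined by ``and`` intersect. Supported clauses::

        name CA            name OE1,OE2
        resid 177-185      resid 115, 181
        chain A            sidechain       heavy       all

    Typical uses: ``"name CA and resid 177-185"`` (Cα of the WPD loop),
    ``"resid 179 and sidechain"`` (side-chain heavy atoms of Trp179).
    The result is ordered by ascending (chain, residue number, atom name)
    and never silently empty.
    """
    matched: set[int] | None = None
    for clause in re.split(r"\band\b", spec):
        clause = clause.strip()
        if not clause:
            continue
        hits = _parse_clause(clause, topology)
        matched = hits if matched is None else matched & hits
    if matched is None:
        raise SelectionError(f"no clauses in selection {spec!r}")
    if not matched:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    order = sorted(
        matched,
        key=lambda i: (topology.atoms[i].chain_id,
                       topology.atoms[i].residue_number,
                       topology.atoms[i].atom_name),
    )
    return Selection(tuple(order))


def ca_selection(topology: StructureModel) -> Selection:
    """All Cα atoms — the default superposition fit set."""
    return select(topology, "name CA")


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _check_fit_geometry(pts: np.ndarray) -> None:
    if pts.shape[0] < 3:
        raise DegenerateFitError(f"fit set has {pts.shape[0]} atoms; need >= 3")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateFitError("fit atoms are (nearly) collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit: Selection | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Both are A×3 arrays over the same atoms; ``fit`` restricts the atoms
    used to determine the transform (default: all). Returns
    ``(aligned_coords, rotation, translation, rmsd)`` where
    ``aligned = mobile @ rotation.T + translation`` and ``rmsd`` is over the
    fit atoms. The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise CongruenceError("mobile and reference must have identical shape")
    idx = fit.indices if fit is not None else np.arange(mobile.shape[0])
    P = mobile[idx]
    Q = reference[idx]
    _check_fit_geometry(P)
    _check_fit_geometry(Q)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    # Kabsch via SVD of the covariance; proper rotation enforced.
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    aligned = mobile @ R.T + t
    diff = aligned[idx] - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(idx)))
    return aligned, R, t, rmsd


def align_ensemble(ensemble: Ensemble, reference: StructureModel,
                   fit: Selection | None = None) -> Ensemble:
    """Superpose every frame onto the reference (default fit: all Cα)."""
    if fit is None:
        fit = ca_selection(ensemble.topology)
    ref_coords = reference.coords
    if ref_coords.shape != (ensemble.n_atoms, 3):
        raise CongruenceError("reference atom count differs from ensemble")
    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        out[f], _, _, _ = kabsch_superpose(ensemble.coords[f], ref_coords, fit)
    return Ensemble(ensemble.topology, out, ensemble.times.copy())


def rmsd_series(ensemble: Ensemble, reference: StructureModel,
                fit: Selection | None = None) -> np.ndarray:
    """Per-frame Cα (or custom-selection) RMSD to a reference after superposition.

    Returns an F×2 array of (time ps, rmsd Å).
    """
    if fit is None:
        fit = ca_selection(ensemble.topology)
    ref_coords = reference.coords
    if ref_coords.shape != (ensemble.n_atoms, 3):
        raise CongruenceError("reference atom count differs from ensemble")
    out = np.empty((ensemble.n_frames, 2))
    for f in range(ensemble.n_frames):
        _, _, _, r = kabsch_superpose(ensemble.coords[f], ref_coords, fit)
        out[f] = (ensemble.times[f], r)
    return out


def slice_frames(ensemble: Ensemble, t_start: float, t_end: float,
                 stride: int = 1) -> Ensemble:
    """Keep frames with t_start <= time <= t_end (closed-closed), every
    ``stride``-th of the survivors."""
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    mask = (ensemble.times >= t_start) & (ensemble.times <= t_end)
    keep = np.nonzero(mask)[0][::stride]
    if keep.size == 0:
        raise ValueError(
            f"no frames in window [{t_start}, {t_end}] ps "
            f"(ensemble spans [{ensemble.times[0]}, {ensemble.times[-1]}])"
        )
    return Ensemble(ensemble.topology, ensemble.coords[keep].copy(),
                    ensemble.times[keep].copy())
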
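"""Synthetic ensembles with planted, recoverable structure.

Every analysis stage in this package (PCA, cross-correlation, the weighted
residue network and its communities, H-bond occupancy) is exercised on
ensembles generated here, where the ground truth is known exactly:

* frames are Gaussian fluctuations of a Cα bead chain around a reference,
  with a block-structured displacement correlation (intra-block ``rho_in``,
  inter-block ``rho_out``, optional per-block-pair coupling overrides);
* a two-state pair of ensembles differs only by the removal of one
  inter-block coupling — a minimal mimic of an apo vs. allosteric-ligand
  contrast in which the information flow between two structural communities
  is switched off;
* a donor/acceptor fixture plants an exact hydrogen-bond occupancy.

The generator contains no physics: it is a statistical stand-in whose whole
purpose is that the planted parameters are the right answers downstream.

Correlations are isotropic: the same residue-residue correlation applies
independently on x, y and z, so the 3-D displacement dot-product
correlation used by the cross-correlation stage equals the planted value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import SpecError
from .structure_io import Atom, Ensemble, StructureModel

#: Cα–Cα virtual bond length of the bead chain, Å.
CA_CA_BOND = 3.8
#: Axis-to-axis distance between adjacent folded helical segments, Å. At
#: this spacing neighbouring segments share a sparse contact interface
#: (about ten Cα pairs inside the default 8 Å cutoff) while non-adjacent
#: segments have none — the dense-intra / sparse-inter topology of packed
#: secondary-structure elements.
SEGMENT_SPACING = 10.0


def derive_seeds(seed: int, n: int) -> list[int]:
    """Split one global seed into ``n`` independent sub-seeds (< 2**31).

    Uses numpy's SeedSequence spawning, so sub-streams are independent and
    the mapping is stable across runs and platforms.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Reference geometries
# ---------------------------------------------------------------------------

def make_reference_chain(n_residues: int, geometry: str = "extended",
                         chain_id: str = "A") -> StructureModel:
    """Cα-only bead chain with idealized geometry.

    ``extended`` places beads on a straight line 3.8 Å apart; ``helix`` uses
    an ideal α-helical Cα trace (radius 2.3 Å, rise 1.5 Å, 100°/residue), so
    i,i+4 pairs fall within 6.5 Å as in a real helix.
    """
    if n_residues < 2:
        raise SpecError("a chain needs at least 2 residues")
    if geometry == "extended":
        xyz = np.zeros((n_residues, 3))
        xyz[:, 0] = np.arange(n_residues) * CA_CA_BOND
    elif geometry == "helix":
        radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
        i = np.arange(n_residues)
        xyz = np.stack([radius * np.cos(i * twist),
                        radius * np.sin(i * twist),
                        rise * i], axis=1)
    else:
        raise SpecError(f"unknown geometry {geometry!r}")
    return _beads_to_model(xyz, chain_id)


def _beads_to_model(xyz: np.ndarray, chain_id: str = "A") -> StructureModel:
    atoms = [
        Atom(serial=i + 1, atom_name="CA", residue_name="GLY",
             chain_id=chain_id, residue_number=i + 1, element="C",
             position=xyz[i].copy())
        for i in range(xyz.shape[0])
    ]
    return StructureModel(atoms)


def contiguous_blocks(sizes: list[int] | tuple[int, ...]) -> tuple[tuple[int, ...], ...]:
    """Partition residues 1..sum(sizes) into sequence-contiguous blocks."""
    blocks = []
    start = 1
    for s in sizes:
        blocks.append(tuple(range(start, start + s)))
        start += s
    return tuple(blocks)


# ---------------------------------------------------------------------------
# Block-correlated Gaussian ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockCovSpec:
    """Planted block-correlation model for a Cα bead chain.

    ``blocks`` must partition residues 1..n_residues exactly (1-based residue
    numbers). Displacement correlation is ``rho_in`` within a block,
    ``rho_out`` between blocks, with optional per-block-pair overrides
    ``coupled_pairs`` = [(block_i, block_j, rho_pair), ...] (0-based block
    indices). ``sigma`` is the per-residue displacement s.d. in Å.
    """

    n_residues: int
    blocks: tuple[tuple[int, ...], ...]
    rho_in: float = 0.8
    rho_out: float = 0.1
    sigma: float = 0.5
    coupled_pairs: tuple[tuple[int, int, float], ...] = ()
    n_frames: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        flat = sorted(r for b in self.blocks for r in b)
        if flat != list(range(1, self.n_residues + 1)):
            raise SpecError("blocks must partition residues 1..n_residues exactly")
        if not 0.0 <= self.rho_in < 1.0:
            raise SpecError("rho_in must be in [0, 1)")
        if not 0.0 <= self.rho_out <= self.rho_in:
            raise SpecError("need 0 <= rho_out <= rho_in (PSD factor model)")
        for bi, bj, rho in self.coupled_pairs:
            if not (0 <= bi < len(self.blocks) and 0 <= bj < len(self.blocks)):
                raise SpecError(f"coupled pair ({bi},{bj}) references unknown block")
            if bi == bj:
                raise SpecError("coupled pairs must join two distinct blocks")
            if not 0.0 <= rho <= self.rho_in:
                raise SpecError("pair coupling must be in [0, rho_in]")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if self.sigma < 0:
            raise SpecError("sigma must be >= 0")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self) -> np.ndarray:
        """0-based block index per residue (length n_residues)."""
        out = np.empty(self.n_residues, dtype=int)
        for b, members in enumerate(self.blocks):
            for r in members:
                out[r - 1] = b
        return out


def planted_correlation(spec: BlockCovSpec) -> np.ndarray:
    """The exact N×N residue displacement correlation matrix being planted."""
    block = spec.block_of()
    same = block[:, None] == block[None, :]
    R = np.where(same, spec.rho_in, spec.rho_out)
    for bi, bj, rho in spec.coupled_pairs:
        mask = ((block[:, None] == bi) & (block[None, :] == bj)) | \
               ((block[:, None] == bj) & (block[None, :] == bi))
        R[mask] = rho
    np.fill_diagonal(R, 1.0)
    return R


def make_block_reference(spec: BlockCovSpec, chain_id: str = "A") -> StructureModel:
    """Fold the bead chain so sequence-contiguous blocks become spatially
    adjacent segments of a helix-bundle ring.

    Each block is an ideal α-helical Cα segment (axis along z); segment
    axes sit on a circle so that neighbouring segments (including
    last-to-first) share a sparse contact interface while non-neighbouring
    segments have none. Within a segment the helical trace gives dense
    i±2..4 contacts. This reproduces the topology the network stage
    assumes — strong intra-block connectivity, few interface edges, and a
    ring that offers alternative routes around any single block-block
    interface so a severed coupling can reroute betweenness.
    """
    B = spec.n_blocks
    N = spec.n_residues
    xyz = np.zeros((N, 3))
    radius_h, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    if B == 1:
        i = np.arange(N)
        xyz[:] = np.stack([radius_h * np.cos(i * twist),
                           radius_h * np.sin(i * twist),
                           rise * i], axis=1)
    else:
        ring = SEGMENT_SPACING / (2.0 * np.sin(np.pi / B))
        for b, members in enumerate(spec.blocks):
            theta = 2.0 * np.pi * b / B
            cx, cy = ring * np.cos(theta), ring * np.sin(theta)
            n_b = len(members)
            i = np.arange(n_b)
            z = rise * i - rise * (n_b - 1) / 2.0
            for k, r in enumerate(members):
                xyz[r - 1] = (cx + radius_h * np.cos(i[k] * twist),
                              cy + radius_h * np.sin(i[k] * twist),
                              z[k])
    return _beads_to_model(xyz, chain_id)


def sample_ensemble(reference: StructureModel, spec: BlockCovSpec,
                    dt: float = 1.0) -> Ensemble:
    """Draw frames = reference + correlated Gaussian displacements.

    The displacement of residue i along each axis is jointly Gaussian with
    the planted correlation matrix and s.d. ``sigma``; axes are independent.
    Sampling goes through the symmetric square root of the correlation
    matrix, so the planted covariance is reproduced exactly in expectation.
    Deterministic for a given seed.
    """
    if reference.n_atoms != spec.n_residues:
        raise SpecError(
            f"reference has {reference.n_atoms} atoms but spec expects "
            f"{spec.n_residues} residues (Cα-only chain)"
        )
    R = planted_correlation(spec)
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise SpecError(
            f"planted correlation matrix is not positive semidefinite "
            f"(min eigenvalue {w.min():.3e}); weaken the couplings"
        )
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n_frames, spec.n_residues, 3))
    disp = spec.sigma * np.einsum("nk,fkc->fnc", L, Z)
    coords = reference.coords[None, :, :] + disp
    times = np.arange(spec.n_frames, dtype=float) * dt
    return Ensemble(reference, coords, times)


# ---------------------------------------------------------------------------
# Two-state (apo vs. bound mimic) pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateSpec:
    """A pair of ensembles differing by one severed inter-block coupling.

    State A is sampled from ``base``; state B from ``base`` with the
    coupling of ``severed_pair`` reduced to ``rho_out`` — the planted
    analogue of an allosteric ligand decoupling two communities.
    """

    base: BlockCovSpec
    severed_pair: tuple[int, int]
    seeds: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        pairs = {(bi, bj) for bi, bj, _ in self.base.coupled_pairs}
        pairs |= {(bj, bi) for bi, bj in pairs}
        if tuple(self.severed_pair) not in pairs:
            raise SpecError(
                f"severed_pair {self.severed_pair} is not among "
                f"base.coupled_pairs {self.base.coupled_pairs}"
            )


def severed_spec(spec: TwoStateSpec) -> BlockCovSpec:
    """The state-B specification: severed coupling dropped to rho_out."""
    si, sj = spec.severed_pair
    new_pairs = tuple(
        (bi, bj, spec.base.rho_out) if {bi, bj} == {si, sj} else (bi, bj, rho)
        for bi, bj, rho in spec.base.coupled_pairs
    )
    return replace(spec.base, coupled_pairs=new_pairs, seed=spec.seeds[1])


def make_state_pair(spec: TwoStateSpec,
                    reference: StructureModel | None = None,
                    dt: float = 1.0) -> tuple[Ensemble, Ensemble]:
    """Sample the (A = intact, B = severed) ensemble pair on a shared reference."""
    if reference is None:
        reference = make_block_reference(spec.base)
    spec_a = replace(spec.base, seed=spec.seeds[0])
    spec_b = severed_spec(spec)
    return (sample_ensemble(reference, spec_a, dt=dt),
            sample_ensemble(reference, spec_b, dt=dt))


# ---------------------------------------------------------------------------
# Planted hydrogen-bond occupancy fixture
# ---------------------------------------------------------------------------

def plant_distance_series(n_frames: int, occupancy: float,
                          d_bound: float = 2.8, d_unbound: float = 6.0,
                          seed: int = 0) -> Ensemble:
    """Donor/acceptor fixture with an exact planted H-bond occupancy.

    The topology is a 4-atom fixture: donor heavy atom NE and its hydrogen
    HE on residue 1 (ARG), acceptor OE1 and its antecedent CD on residue 2
    (GLU). Exactly ``round(occupancy * n_frames)`` frames (chosen at random
    positions in the series) place the donor-acceptor distance at
    ``d_bound`` with an ideal (180°) D-H···A angle; the rest sit at
    ``d_unbound``.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise SpecError("occupancy must be in [0, 1]")
    if n_frames < 1:
        raise SpecError("n_frames must be >= 1")
    if not d_bound < d_unbound:
        raise SpecError("d_bound must be smaller than d_unbound")
    atoms = [
        Atom(1, "NE", "ARG", "A", 1, "N", np.zeros(3)),
        Atom(2, "HE", "ARG", "A", 1, "H", np.array([1.0, 0.0, 0.0])),
        Atom(3, "OE1", "GLU", "A", 2, "O", np.array([d_unbound, 0.0, 0.0])),
        Atom(4, "CD", "GLU", "A", 2, "C", np.array([d_unbound + 1.2, 0.9, 0.0])),
    ]
    topo = StructureModel(atoms)
    n_bound = int(round(occupancy * n_frames))
    rng = np.random.default_rng(seed)
    bound = np.zeros(n_frames, dtype=bool)
    bound[rng.permutation(n_frames)[:n_bound]] = True
    coords = np.tile(topo.coords, (n_frames, 1, 1))
    coords[bound, 2, 0] = d_bound        # acceptor OE1 moves in along x
    coords[bound, 3, 0] = d_bound + 1.2  # its antecedent follows
    times = np.arange(n_frames, dtype=float)
    return Ensemble(topo, coords, times)
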
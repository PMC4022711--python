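# Methods

## Scope and model

`allopath` analyses conformational ensembles of a protein — F frames of A
atoms in Å, with ps frame times — to locate channels of allosteric
communication. The analysis chain is: remove rigid-body motion by
least-squares superposition onto a reference structure; diagonalize the
positional covariance of a selected Cα subset (essential dynamics);
compute the dynamic cross-correlation matrix (DCCM) of Cα displacement
vectors; build a residue-interaction network from persistent contacts
weighted by motion correlation; partition it into communities; and compare
two states (e.g. apo vs. ligand-bound) through differential correlation
maps and inter-community betweenness changes. Molecular dynamics itself is
out of scope: the package consumes ensembles, it does not generate physics.

## Superposition and PCA

Superposition is the Kabsch construction (SVD of the 3×3 cross-covariance
with a proper-rotation correction); fits require at least three
non-collinear atoms and default to all Cα atoms. PCA uses the population
(1/F) normalization, matching the time-average definition of the
covariance; eigenvalues are therefore mean-square amplitudes in Ų.
Centring is at the post-alignment ensemble mean — the reference structure
only fixes the frame of reference. Eigenvector signs are fixed by making
each vector's largest-magnitude component positive, since projections are
sign-sensitive and no convention is otherwise canonical.

## DCCM and the alignment caveat

`C_ij` is the normalized time average of the 3-D displacement dot product
(not a per-axis average). Zero-variance residues get zero off-diagonal
entries with a warning, diagonal 1 by convention.

Superposition is itself a filter: removing the best-fit rigid transform of
every frame subtracts the fluctuating common mode, which *shifts*
correlations (a well-known artifact — uniformly weakly-correlated systems
acquire spurious anti-correlations after fitting, and strong collective
couplings are attenuated). For real trajectories alignment is unavoidable
and the default. Synthetic ensembles from this package are generated
without any rigid-body motion, so for them `compute_dccm(...,
reference=None)` skips alignment and the measured DCCM equals the planted
correlation to sampling error; the planted-value checks and two-state
benchmarks use that mode. This is a deliberate, documented asymmetry, not
an inconsistency: the planted ground truth is defined in the generator's
frame.

## Network construction

Nodes are residues (one Cα each). An edge joins residues in contact in at
least 75% of frames; the contact criterion is any heavy-atom pair within
4.5 Å, falling back to Cα–Cα ≤ 8.0 Å for Cα-only ensembles, with sequence
neighbours |i−j| ≤ 1 excluded. None of these numbers is canonical in the
literature; all are configurable. Edge length is `w_ij = −log|C_ij|`
(strongly correlated contacts are short, so shortest paths follow strong
coupling chains), with `1 − |C_ij|` available as an alternative. Edges
with `|C_ij| < 1e-4` are dropped (their length diverges).

Shortest paths use Floyd–Warshall with co-optimal path counting (ties
within a relative 1e-12). Edge betweenness uses Brandes' dependency
accumulation on Dijkstra DAGs with fractional credit to co-optimal paths;
each unordered node pair contributes exactly 1 split over its shortest
paths. Both algorithms are implemented here and are cross-checked in the
test suite against independent oracles (per-source array Dijkstra,
exhaustive simple-path enumeration, networkx).

## Communities

Modularity is `Q = Σᵢ (e_ii − a_i²)` computed on coupling-strength weights
`|C_ij|`, so "stronger intraconnections" raise Q; an unweighted variant is
available. Community detection is Girvan–Newman: iteratively remove the
most overloaded edge, recomputing betweenness after every removal, track
the connected-component partition's Q on the intact network, and return
the best partition seen.

The removal score is betweenness divided by coupling strength — Newman's
weighted-network generalization of the algorithm, in which an edge of
weight w behaves as w parallel unit edges. The plain (unweighted) rule is
available but performs poorly on strongly weighted networks: shortest
paths funnel through the single cheapest interface crossing, so the strong
feeder edges just inside an interface accumulate more raw betweenness than
the weak interface edge itself and are removed first, fragmenting
communities. The weighted rule removes weak, overloaded edges — the
community interfaces — and recovers planted partitions exactly in the
benchmarks. Ties are broken toward the lexicographically smallest node
pair, making the result independent of input order.

Modularity maximization has a known resolution behaviour: homogeneous
chain-like networks (a single uniform helix) acquire positive-Q splits
into sequence-contiguous chunks even though no block structure was
planted. This is a property of Q, not a bug; downstream interpretation
should treat communities of structureless regions with caution.

A degeneracy step can coarsen partitions, either by an explicit label
mapping or a minimum-size rule (small communities are absorbed, smallest
first, into the neighbour with the strongest total inter-community
coupling). Ball-and-stick summaries report community sizes and summed
cross-community edge betweenness; an exclusion list drops residues (e.g. a
flexible terminus) before summarizing. Two-state comparison maps community
labels across states and reports signed stick differences sorted by
magnitude.

## Geometry probes

Distances and torsions are internal coordinates and computed without
superposition. The hydrogen-bond criterion defaults to donor–acceptor
heavy-atom distance ≤ 3.5 Å and, when a hydrogen is present, D–H···A angle
≥ 135° — common MD-analysis practice, exposed as parameters because
reported occupancies depend on them; a distance-only mode covers ensembles
without hydrogens. Ambiguous carboxylate-style atom names ("OE" of a
glutamate) match all atoms with that prefix and the closest one counts.
Torsions use the standard atan2 construction with range (−180°, 180°];
collinear triples raise an error rather than returning an arbitrary angle.

## Synthetic ensembles: what they emulate and what they do not

The generator produces frames = reference + correlated Gaussian
displacement. Displacement correlations are isotropic (the same
residue-residue correlation on x, y, z independently), built by direct
construction of the N×N correlation matrix — `rho_in` within blocks
(default 0.8), `rho_out` between (default 0.1), optional per-block-pair
overrides — checked positive-semidefinite by eigendecomposition and
sampled through its symmetric square root, so the planted DCCM is exact in
expectation. Default per-residue amplitude `sigma` is 0.5 Å and the
default benchmark size is 5000 frames, which puts the sampling error of a
single correlation entry near ±0.01 (Fisher-z) — small against the 0.1 /
0.8 contrast being recovered.

Reference geometries: an ideal α-helical Cα trace (radius 2.3 Å, rise
1.5 Å, 100°/residue) or an extended chain, both with 3.8 Å virtual bonds.
Block-structured specs fold into a ring bundle of helical segments with
10 Å axis spacing: each block then has dense i±2..4 internal contacts, ring-
adjacent blocks share a sparse (~10-edge) interface, and non-adjacent
blocks have none. The ring topology matters for the two-state benchmark:
it provides alternative routes around any single interface, so severing a
coupling visibly reroutes betweenness instead of merely disconnecting the
graph. The two-state default couples one adjacent block pair at rho 0.6 —
midway between background and intra-block coupling, a realistic "strong
allosteric link" — and severs it to the background 0.1 in state B.

The generator contains no physics: no excluded volume, no bond-length
fluctuation realism, no anisotropy, no time correlation between frames
(frames are i.i.d., so it cannot test convergence/autocorrelation issues
of real trajectories), and no side chains (Cα beads only, so the
heavy-atom contact mode and hydrogen-aware H-bond gates are exercised by
purpose-built fixtures instead). Passing the planted-recovery benchmarks
therefore shows the analysis machinery is correct and self-consistent, not
that any particular real system's communities are right.

The planted-occupancy fixture places a 4-atom donor/hydrogen/acceptor/
antecedent system at an ideal 180° approach in exactly
`round(occupancy × n_frames)` randomly positioned frames; the occupancy
probe must read the planted fraction back exactly.

All randomness flows from explicit integer seeds; one global seed expands
to per-purpose sub-seeds via numpy `SeedSequence` spawning (stable across
platforms, all below 2³¹).

## Problem sizes and numerical choices

Benchmarks use 24–48 residue bead chains with 2000–5000 frames and 10
seeds per condition — sizes at which exact Girvan–Newman (betweenness
recomputed after every single removal) and the exhaustive test oracles
(all-partition modularity search to n = 8, all-simple-path enumeration to
n = 10) run in seconds while leaving the planted contrasts statistically
unambiguous. Shortest-path ties use a relative tolerance of 1e-12;
eigenvalue clips at −1e-8 guard PSD checks; correlation entries are
clipped to [−1, 1] against rounding. PDB coordinates round-trip at the
format's 1e-3 Å precision.

## Known limitations

- The −log|C| edge length diverges as |C| → 0; the 1e-4 floor drops such
  edges rather than keeping near-infinite lengths.
- Exact Girvan–Newman is O(E²·V·…) and intended for single-domain proteins
  (N ≈ 300); very large systems would need an approximate scheme.
- Betweenness under co-optimal ties is fractional by choice; integer
  path-count conventions would differ on tied graphs.
- Modularity's resolution behaviour (see above) can over-split homogeneous
  regions and cannot see communities below its resolution limit.
- The DCCM is a linear, instantaneous correlation; time-lagged or
  mutual-information couplings are out of scope.
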
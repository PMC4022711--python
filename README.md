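# allopath

Dynamic weighted community analysis of protein conformational ensembles.

Allosteric inhibitors act at a distance: a ligand binding ~20 Å from a
catalytic site can lock a catalytic loop open and silence the enzyme. To
trace *how* such a signal propagates, the standard post-simulation battery
treats the protein as a dynamical network: residues whose motions are
correlated and who stay in physical contact form channels of information
flow, and perturbations show up as rewired channels. `allopath` implements
that battery as a tested, reusable library:

- **Structure/ensemble I/O** — multi-model PDB reader/writer (one frame per
  `MODEL`), atom selections, Kabsch superposition, RMSD series, frame
  windowing.
- **Essential dynamics** — PCA of the positional covariance
  `C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩` over selected Cα atoms; eigenvalues λᵢ are
  collective-mode amplitudes, projections `pᵢ = Vᵢ · (M − ⟨x⟩)` locate each
  frame along mode Vᵢ.
- **Cross-correlation** — the DCCM
  `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩)` of Cα displacement vectors
  (+1 correlated, −1 anti-correlated, ~0 independent), plus state-difference
  maps and per-community-pair summaries.
- **Network analysis** — persistent-contact residue graph; edge lengths
  `w_ij = −log|C_ij|` (strong coupling = short edge); all-pairs shortest
  paths (Floyd–Warshall with co-optimal path counts); fractional edge
  betweenness; Girvan–Newman community detection maximizing modularity
  `Q = Σᵢ (e_ii − a_i²)`; community merging; ball-and-stick community
  graphs whose stick values (summed cross-edge betweenness) quantify
  inter-community information flow; two-state stick comparison.
- **Geometry probes** — atom/group distance series, hydrogen-bond occupancy
  under a distance(+angle) criterion, torsion-angle series (ring flips).
- **Synthetic ensembles** — Gaussian fluctuations with *planted*
  block-correlation structure, two-state severed-coupling pairs, and exact
  planted H-bond occupancy, so every stage has a recoverable ground truth
  without running molecular dynamics.

## Worked example

Plant four correlated residue blocks, recover them as network communities:

```python
import allopath as ap

spec = ap.BlockCovSpec(
    n_residues=48, blocks=ap.contiguous_blocks([12, 12, 12, 12]),
    rho_in=0.8, rho_out=0.1, n_frames=5000, seed=3)
reference = ap.make_block_reference(spec)
ensemble = ap.sample_ensemble(reference, spec)

dccm = ap.compute_dccm(ensemble)
network = ap.weight_edges(ap.build_contact_graph(ensemble), dccm)
partition = ap.girvan_newman(network)
print(partition.q, partition.n_communities())
```

prints

```
0.7118905861259568 4
```

a modularity of ~0.71 with exactly the four planted 12-residue communities
(`examples/03_community_network.py` shows the full run including the
ball-and-stick summary; the other `examples/*.py` scripts cover PCA mode
recovery, the two-state severed-coupling contrast and the geometry probes,
each printing the numbers it checks).

For shell use the same workflow is available as a thin CLI:

```bash
allopath synth --spec spec.yaml --out traj.pdb
allopath run --config run.yaml          # full per-state pipeline + compare
allopath compare --config run.yaml --a apo --b bound
```

Exit codes: 0 success, 2 configuration error, 3 data error.

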
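"""Generate a block-correlated synthetic ensemble and verify its planted
cross-correlation structure.

Two groups of 12 residues fluctuate around a folded reference with strong
intra-group correlation (0.8) and weak inter-group correlation (0.1). The
dynamic cross-correlation matrix computed from the sampled frames should
read those numbers back.
"""

import numpy as np

import allopath as ap

spec = ap.BlockCovSpec(
    n_residues=24,
    blocks=ap.contiguous_blocks([12, 12]),
    rho_in=0.8, rho_out=0.1, sigma=0.5,
    n_frames=5000, seed=1,
)
reference = ap.make_block_reference(spec)
ensemble = ap.sample_ensemble(reference, spec)
print(f"sampled {ensemble.n_frames} frames x {ensemble.n_atoms} residues")

dccm = ap.compute_dccm(ensemble)  # frames share a common frame: no alignment
C = dccm.values
intra = C[:12, :12][np.triu_indices(12, 1)]
inter = C[:12, 12:].ravel()
print(f"mean intra-block C_ij = {intra.mean():.3f}  (planted 0.8)")
print(f"mean inter-block C_ij = {inter.mean():.3f}  (planted 0.1)")
# Close agreement means the generator and the correlation stage are
# mutually consistent: the DCCM recovers exactly what was planted.
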
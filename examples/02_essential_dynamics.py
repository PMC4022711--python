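"""Essential-dynamics PCA: plant one dominant collective mode and recover it.

Frames are built as reference + amplitude * mode + noise, with the mode
orthogonal to rigid-body motions. The leading principal component of the
positional covariance should align with the planted mode, and the variance
profile shows how much of the motion the first components capture.
"""

import numpy as np

import allopath as ap

rng = np.random.default_rng(2)
n = 24
reference = ap.make_reference_chain(n, "helix")

# a random internal mode: project out the 6 rigid-body directions
mode = rng.standard_normal(3 * n)
c = reference.coords - reference.coords.mean(axis=0)
rigid = []
for ax in range(3):
    t = np.zeros((n, 3)); t[:, ax] = 1.0
    rigid.append(t.ravel())
    e = np.zeros(3); e[ax] = 1.0
    rigid.append(np.cross(np.tile(e, (n, 1)), c).ravel())
basis = np.linalg.qr(np.array(rigid).T)[0]
mode -= basis @ (basis.T @ mode)
mode /= np.linalg.norm(mode)

n_frames = 2000
amplitudes = rng.standard_normal(n_frames) * 2.0
noise = rng.standard_normal((n_frames, 3 * n)) * 0.1
coords = reference.coords[None] + (
    amplitudes[:, None] * mode[None] + noise).reshape(n_frames, n, 3)
ensemble = ap.Ensemble(reference, coords, np.arange(n_frames, dtype=float))

model = ap.fit_pca(ensemble, ap.ca_selection(reference), reference)
cos = abs(float(model.eigenvectors[:, 0] @ mode))
profile = ap.variance_profile(model, 5)
proj = ap.project_ensemble(model, ensemble, n_pcs=1)

print(f"|cos(PC1, planted mode)| = {cos:.4f}   (1.0 = perfect recovery)")
print(f"cumulative variance of first 5 PCs: {np.round(profile, 3)}")
print(f"PC1 projection s.d. = {proj[:, 0].std():.2f} Å "
      f"(planted amplitude s.d. 2.0 Å)")
# PC1 matches the planted mode and carries nearly all the variance; the
# projection spread reproduces the planted amplitude distribution.
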
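"""Two-state contrast: locate a severed inter-community coupling.

State A couples blocks 0 and 1 at rho = 0.6 (a strong allosteric link);
state B severs that coupling to the background 0.1 — a minimal mimic of an
allosteric ligand decoupling two structural communities. Both the
differential cross-correlation map and the drop in stick betweenness
should point at the (0, 1) interface.
"""

import allopath as ap

base = ap.BlockCovSpec(
    n_residues=48,
    blocks=ap.contiguous_blocks([12, 12, 12, 12]),
    coupled_pairs=((0, 1, 0.6),),
    n_frames=5000, seed=0,
)
pair = ap.TwoStateSpec(base=base, severed_pair=(0, 1), seeds=(11, 12))
state_a, state_b = ap.make_state_pair(pair)

dccm_a = ap.compute_dccm(state_a)
dccm_b = ap.compute_dccm(state_b)
diff = ap.differential_dccm(dccm_b, dccm_a)

truth = {("A", r): (r - 1) // 12 for r in range(1, 49)}
blocks = ap.block_summary(diff, truth, dccm_a.residue_labels)
print("mean |dC| per community pair (B - A):")
for (p, q), v in sorted(blocks.items(), key=lambda t: -t[1])[:4]:
    print(f"  {p} - {q}: {v:.3f}")

graphs = []
for ens, dccm in ((state_a, dccm_a), (state_b, dccm_b)):
    net = ap.weight_edges(ap.build_contact_graph(ens), dccm)
    bt = ap.edge_betweenness(net)
    part = ap.CommunityPartition(truth, ap.modularity(net, truth))
    graphs.append(ap.community_graph(net, part, bt))

print("stick betweenness differences (B - A), largest first:")
for (p, q), v in ap.compare_networks(graphs[0], graphs[1])[:4]:
    print(f"  {p} - {q}: {v:+.0f}")
# The (0, 1) pair tops both lists: its correlations collapse and the
# information flow across its interface reroutes around the ring — the
# same signature the method uses to localize allosteric decoupling.
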
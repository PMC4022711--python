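"""Weighted residue network and Girvan-Newman communities on planted blocks.

Four 12-residue blocks fold into a helix-bundle ring; residues are
correlated strongly within blocks and weakly across. The contact graph is
weighted by motion correlation (edge length -log|C_ij|), partitioned by
Girvan-Newman at maximal modularity, and summarized as a ball-and-stick
community graph. The partition should match the planted blocks exactly.
"""

import allopath as ap

spec = ap.BlockCovSpec(
    n_residues=48,
    blocks=ap.contiguous_blocks([12, 12, 12, 12]),
    rho_in=0.8, rho_out=0.1,
    n_frames=5000, seed=3,
)
reference = ap.make_block_reference(spec)
ensemble = ap.sample_ensemble(reference, spec)

dccm = ap.compute_dccm(ensemble)
contacts = ap.build_contact_graph(ensemble)          # Cα-Cα 8 Å, 75% persistence
network = ap.weight_edges(contacts, dccm)            # length = -log|C_ij|
betweenness = ap.edge_betweenness(network)
partition = ap.girvan_newman(network)

print(f"{len(network.nodes)} nodes, {len(network.edges)} persistent edges")
print(f"modularity Q = {partition.q:.3f}, "
      f"{partition.n_communities()} communities")
for label, members in partition.communities().items():
    resnums = [r for _, r in members]
    print(f"  community {label}: residues {min(resnums)}-{max(resnums)} "
          f"({len(members)} residues)")

graph = ap.community_graph(network, partition, betweenness)
print("stick betweenness (information flow between communities):")
for (p, q), value in sorted(graph.sticks.items()):
    print(f"  {p} - {q}: {value:.0f}")
# Communities coincide with the planted 12-residue blocks; sticks join
# only ring-adjacent blocks, whose interfaces carry the shortest paths.
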
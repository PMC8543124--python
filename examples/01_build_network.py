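"""Build an amino-acid network at one cutoff and read packing measures.

Three single-atom residues on a line (x = 0, 4, 8 Å) at a 5 Å cutoff: the
middle residue touches both ends (degree 2), the ends only the middle
(degree 1).  Degree counts residue neighbors; weight counts the qualifying
atom pairs behind those links.
"""

from aanet import build_aan, generate_synthetic_structure, line_spec

structure = generate_synthetic_structure(line_spec([0.0, 4.0, 8.0]))
aan = build_aan(structure, cutoff=5)

print(f"{len(structure)} residues, cutoff {aan.cutoff} Å, {len(aan.edges)} links")
for i, residue in enumerate(structure.residues):
    print(f"  {residue.key.label}: degree={aan.node_degree(i)} "
          f"weight={aan.node_weight(i)}")
print("handshake: sum of node weights =", aan.weights().sum(),
      "= 2 x total link weight =", 2 * aan.total_edge_weight())
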
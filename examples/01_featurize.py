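"""Featurize a compound and a protein.

Builds the two compound views (directed molecular graph, Morgan fingerprint)
for aspirin and tokenizes a short kinase fragment, printing the shapes the
encoders consume.
"""

from cpifuse import smiles_to_molgraph, smiles_to_fingerprint, tokenize_protein

aspirin = "CC(=O)Oc1ccccc1C(=O)O"
graph = smiles_to_molgraph(aspirin)
fp = smiles_to_fingerprint(aspirin)  # ECFP4: radius 2, 2048 bits
tokens = tokenize_protein("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", max_len=500)

print(f"aspirin: {graph.n_atoms} heavy atoms, "
      f"{graph.n_directed_bonds} directed bonds "
      f"({graph.n_directed_bonds // 2} chemical bonds)")
print(f"atom feature vector length: {graph.atom_feats.shape[1]}")
print(f"bond feature vector length: {graph.bond_feats.shape[1]}")
print(f"fingerprint: {int(fp.bits.sum())} of {fp.n_bits} bits set")
print(f"protein tokens: length {tokens.max_len}, "
      f"{tokens.true_length} residues before padding")
# Each directed bond pair shares its bond features; message passing treats
# the two directions independently so information never backtracks.
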
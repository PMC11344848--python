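"""Assemble peptide sequences into molecules and check their formulas.

Each one-letter sequence becomes a linear peptide: free amine N-terminus,
free acid C-terminus, amide backbone, L stereocenters, free thiols.
"""

from pepsim import assemble_peptide, molecular_formula, residue_smiles

for seq in ["G", "GG", "CGGSGGC"]:
    mol = assemble_peptide(seq)
    counts = molecular_formula(mol)
    formula = "".join(f"{el}{n}" for el, n in sorted(counts.items()))
    print(f"{seq:10s} {formula:18s} {mol.smiles}")

frag = residue_smiles("G", form="internal")
print(f"\ninternal glycine unit: {frag.smiles}  formula {frag.formula}")
print("(the internal residue is the free amino acid minus one water)")
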
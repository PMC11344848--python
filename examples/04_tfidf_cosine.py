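"""Sequence-text similarity: TF-IDF weighted residue counts and cosines.

Each peptide is a bag of residue letters; counts are weighted by smoothed
inverse document frequency over the panel (rare residues count more),
L2-normalized, and compared by cosine. This is the text-based complement
to the chemical fingerprint similarity.
"""

from pepsim import Peptide, tfidf_cosine

panel = [
    Peptide(id="P2", residues="CGGSGGC"),
    Peptide(id="P3", residues="CGSGGSGC"),
    Peptide(id="P4", residues="CQPHPGQTC"),
    Peptide(id="poly-G", residues="GGGGGG"),
]
matrix = tfidf_cosine(panel)
print(matrix.to_dataframe().round(3))
print("\nP2 and P3 share composition (high cosine) even though their")
print("orders differ; P4 introduces residues absent elsewhere (lower)")
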
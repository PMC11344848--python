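# pepsim

Chemical similarity analysis of phage-display peptide panels.

Phage-display selections on a CX10C library (an N- and C-terminal
cysteine flanking ten randomized positions) can yield families of
binders with very different chemistry — for example cyclization-selected
peptides with the consensus motif CPXNX₃PX₃C versus classical linear
streptavidin binders carrying the HPQ/HPM tripeptide. `pepsim`
quantifies how chemically divergent such families are, using three
complementary similarity measures plus motif/logo analytics, and ships a
seeded synthetic panel generator so the whole pipeline is testable
without any proprietary selection output.

It is a library for computational chemists and phage-display
practitioners, with a thin `pepsim` command-line wrapper.

## The methods

1. **Whole-sequence fingerprint similarity.** Each peptide sequence is
   assembled into a linear molecule (amide backbone, free termini,
   neutral protonation, free thiols) and encoded as a MinHashed
   atom-pair fingerprint: for every pair of heavy atoms *i, j* and
   radius *k* ∈ {1..r} a shingle `env_k(i)|d(i,j)|env_k(j)` combines the
   canonical SMILES of the two circular atom environments with their
   topological distance in bonds. The Jaccard similarity
   J(A,B) = |A∩B| / |A∪B| between two shingle sets is estimated as the
   fraction of equal components between MinHash signatures (1 for
   identical, 0 for highly dissimilar); a brute-force exact-Jaccard
   oracle is built in (`exact=True`).
2. **Positional similarity.** For two aligned 12-mers, each of the
   twelve positions contributes the fingerprint Jaccard similarity of
   the two residues as free amino-acid molecules, giving a per-position
   profile of where the chemistry diverges.
3. **TF-IDF cosine similarity.** Each sequence is a bag of residue
   letters; counts are weighted by smoothed inverse document frequency
   idf(t) = ln((1+N)/(1+df(t))) + 1 over the panel, L2-normalized, and
   compared by cosine.

Cross-family averaging reports, per peptide, its mean similarity to the
other family and to its own family, always excluding self-comparisons.
Motif utilities scan for HPQ/HPM and the CPXNX₃PX₃C consensus, build
position frequency matrices, and compute sequence-logo information
content IC(p) = log₂20 − H(p) in bits.

## Worked example

```python
from pepsim import FingerprintParams, FIXTURES, full_similarity

params = FingerprintParams(max_radius=2, signature_length=2048, seed=7)
for a, b in [("P2", "P2"), ("P2", "P3"), ("P2", "P4")]:
    est = full_similarity(FIXTURES[a], FIXTURES[b], params)
    exact = full_similarity(FIXTURES[a], FIXTURES[b], params, exact=True)
    print(a, b, round(est, 4), round(exact, 4))
```

prints

```
P2 P2 1.0 1.0
P2 P3 0.5205 0.5135
P2 P4 0.1294 0.1336
```

P2 (CGGSGGC) is identical to itself (similarity exactly 1), closely
related to P3 (CGSGGSGC, one extra Gly-Ser), and chemically distant from
P4 (CQPHPGQTC). The MinHash estimate tracks the exact set overlap to
within the binomial error of the signature length.

The `examples/` directory holds one short script per capability
(assembly, fingerprints, positional profiles, TF-IDF, motifs/logos, and
the full two-panel comparison). The same pipeline is available from the
shell:

```
pepsim generate --family str_like --n 9 --seed 7 --output str.fasta
pepsim generate --family hpq_like --n 12 --seed 8 --output hpq.fasta
pepsim compare --panel-a str.fasta --panel-b hpq.fasta --output report/
```

which writes similarity-matrix TSVs, per-pair positional profiles, a
per-peptide cross/within-family summary JSON and a manifest that
regenerates the bundle bit-identically.

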
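# Methods

## Peptide-to-molecule conversion

A sequence over the 20 natural amino acids is assembled by concatenating
per-residue SMILES units of the form `N[C@@H](side chain)C(=O)` (glycine
`NCC(=O)`, proline `N1CCC[C@H]1C(=O)`) and appending a terminal `O`, so
consecutive units condense into amide bonds and the chain carries a free
amine N-terminus and free carboxylic acid C-terminus. The free amino
acid of any residue is its internal unit plus `O`, which guarantees the
bookkeeping identity used throughout the tests:

    formula(peptide of length L) = Σ formula(free residue) − (L−1)·H₂O

Choices, and why:

* **Neutral protonation, no zwitterions.** Formulas and canonical SMILES
  become deterministic; ionization state does not affect the heavy-atom
  graph the fingerprint sees.
* **Free thiols.** Cysteines are not paired into disulfides and no
  cyclization linker is modelled: the similarity analysis operates on
  the plain displayed sequence, and whether a family is cyclized enters
  only through its sequence composition.
* **L stereocenters in the SMILES, stripped in the fingerprint.** The
  units carry the natural L configuration, verified by CIP assignment
  ((S) at the alpha carbon except cysteine's (R); Ile (2S,3S), Thr
  (2S,3R)). The fingerprint removes stereo descriptors by default
  (`include_stereo=False`) so environment canonicalization is stable;
  the flag restores them.

RDKit provides SMILES parsing, canonical serialization, the topological
distance matrix and canonical fragment SMILES; the package's own layer
is everything above that.

## MinHashed atom-pair fingerprint

For a molecule with heavy-atom graph G, the shingle set contains, for
every unordered pair of distinct connected atoms (i, j) and every radius
k = 1..`max_radius`, the string `envA|d|envB`: the canonical SMILES of
the radius-k circular environments of the two atoms (lexicographically
ordered), joined with their shortest-path bond distance d. Environments
are rooted at the central atom, so symmetry-equivalent atoms produce
identical strings; a radius exceeding the molecule's diameter saturates
at the whole connected component. Shingles are a set: radii whose
environments have saturated contribute no new elements (for a two-atom
molecule the radius-1 and radius-2 shingles coincide and the set has one
element). Self-pairs are excluded and pairs spanning disconnected
fragments skipped. Hydrogens are implicit — including them would only
inflate every environment string without discriminating peptides.

MinHash signature: component *i* is

    min over shingles s of (a_i · h(s) + b_i) mod 2⁶⁴

where h(s) is the first 8 bytes (little-endian) of BLAKE2b of the UTF-8
shingle and (a_i, b_i) are drawn from `numpy.random.Generator(PCG64(seed))`
with a_i forced odd, making each map a bijection on 64-bit integers. The
family is documented rather than named after any library so signatures
are reproducible cross-platform from this description alone. The
fraction of equal components between two signatures estimates the
Jaccard similarity; the standard error at signature length m is
√(J(1−J)/m) ≈ 0.011 at m = 2048. The estimator is validated against the
in-package brute-force `exact_jaccard` (set intersection over union):
the test suite checks a max absolute error ≤ 0.05 and mean bias within
±0.01 over 50 seeded random 12-mer pairs.

Defaults `max_radius=2`, `signature_length=1024` follow the published
defaults of the atom-pair MinHash fingerprint family; both are
configurable, and every hash is derived from the single `seed`
parameter.

## Similarity methods

* **full_map4** — assemble, shingle, MinHash, estimate Jaccard.
  Self-comparison is exactly 1 (identical signatures). `exact=True`
  switches to the brute-force set Jaccard, intended for small panels.
* **positional_mean** — per aligned position, the Jaccard similarity of
  the two residues as *free amino-acid molecules*; a per-residue
  dictionary of signatures is cached, and residue-identical positions
  short-circuit to exactly 1. The free (rather than backbone-capped)
  form mirrors converting each amino acid on its own to SMILES. The
  scalar matrix entry is the arithmetic mean of the twelve values; the
  profile itself is the primary output and the mean a documented
  convenience.
* **tfidf_cosine** — counts of each residue letter weighted by smoothed
  idf, ln((1+N)/(1+df))+1, L2-normalized, cosine between vectors. These
  are the documented defaults of the standard text-vectorizer
  convention (smooth idf, raw term frequency, Euclidean norm); the test
  suite cross-checks the full matrix against scikit-learn's
  TfidfVectorizer with character tokens. The idf corpus is exactly the
  union of the panels passed to one comparison run, since the families
  are compared jointly.

Cross-family averaging never includes the diagonal; the within-group
mean of a singleton group is reported as undefined (`None`/`null`), not
zero.

## Motifs and logos

Patterns are strings over the residue alphabet plus wildcard `X`;
offsets are 1-based inclusive (peptide-literature convention), and
overlapping matches are all reported. "HPQ/M" is expanded to the two
patterns HPQ and HPM, scanned separately and merged. The consensus flag
requires a 12-mer matching `CPXNXXXPXXXC` at offset 1.

Position frequency matrices count residues per column over an aligned
panel; information content is IC(p) = log₂20 − H(p) bits, bounded by
[0, log₂20 ≈ 4.32]. The small-sample correction
e_n = 19/(2·ln2·n) is off by default — at panel sizes of 9–12 it is
visibly large (~1.5 bits) and whether to apply it is a rendering
convention, so it is an explicit flag. The threshold consensus emits a
residue where its frequency reaches the threshold (default 0.9, must
exceed 0.5 so the winner is unique), else `X`.

## Synthetic panels

The generator emulates the *structure* of selection outputs on a CX10C
library, not their full residue-composition biases:

* `str_like` (default n = 9, the number of unique cyclization-selected
  binders): C, P, N, P, C fixed at positions 1, 2, 4, 8, 12; seven
  uniform positions.
* `hpq_like` (default n = 12, the linear-binder panel size): CX10C
  scaffold, HPQ or HPM by fair seeded coin at a uniform internal offset
  (2..9), never overwriting the terminal cysteines.
* `random`: CX10C with ten uniform internal positions — the naive
  library control; the chance of matching the consensus is (1/20)³ =
  1.25·10⁻⁴ (three extra fixed internal positions).

Randomized positions draw from all 20 residues by default ("any natural
amino acid"), with an exclude-cysteine alphabet available because real
selections can disfavor extra thiols. All draws come from
`PCG64(seed)`; identical spec and seed give byte-identical FASTA.

What passing tests on these panels shows — and does not. The generators
reproduce the motif skeleton (conserved positions, embedded motifs,
scaffold cysteines) and therefore the *qualitative* finding that a
consensus-sharing family is chemically closer to itself than to a
motif-unrelated family, checked over 10 seeds with a ≥ 9/10 margin. They
make no claim to match the real panels' amino-acid usage, positional
covariation or selection-induced biases, so absolute similarity values
on synthetic panels are not predictions of the real families' values.

Printed fixture peptides (P1–P6, vasopressin and its two single-cysteine
variants) are bundled; P1 appears in its source in two spellings
(`CTTRRPYLVCWL` in the table, `CTTEEPYLVCWL` in the text), so both are
kept under distinct ids rather than silently choosing one.

## Numerical and degenerate-input conventions

* Similarities are clipped to [0,1]; full and cosine matrices have an
  exact unit diagonal and are symmetrized before output.
* Molecules with fewer than two heavy atoms yield an empty shingle set
  with a warning; MinHashing an empty set is an error (no signature is
  defined), as is the Jaccard of two empty sets.
* Signatures built with different parameters refuse comparison.
* Matrix TSVs are written with six fixed decimals, and manifests carry
  no timestamps, so a rerun of the same configuration reproduces the
  report bundle byte-for-byte.
* Problem sizes in the test suite (50-pair estimator checks at
  signature length 2048, 10-seed panel comparisons at 9 + 12 peptides,
  1,000-case motif oracle sweeps) were chosen to make the binomial error
  bounds meaningful while keeping the whole suite fast on one CPU.

## Known limitations

* Linear chemistry only: no disulfides, no cyclization linker, no
  non-canonical residues — divergence attributable to the macrocycle
  itself is invisible to the fingerprint and enters only via sequence.
* MinHash accuracy is binomial in the signature length; very similar
  but non-identical molecules need long signatures (or `exact=True`) to
  resolve.
* The positional method compares residues out of context (free amino
  acids), so backbone-environment effects on similarity are not
  captured.
* TF-IDF cosine ignores residue order entirely; anagrams score 1.
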
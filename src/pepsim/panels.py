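"""Seeded synthetic peptide panels and FASTA input/output.

The generators emulate the outputs of a phage-display selection on a
CX10C library (an N- and C-terminal cysteine flanking ten fully
randomized positions, 12 residues total):

* ``str_like`` — cyclization-selected binders matching the consensus
  CPXNXXXPXXXC: C, P, N, P, C fixed at positions 1, 2, 4, 8, 12 and the
  seven X positions uniform over the alphabet.
* ``hpq_like`` — linear binders on the CX10C scaffold with an HPQ or HPM
  tripeptide (fair seeded coin) written at a uniform internal offset, so
  the motif never overwrites the terminal cysteines.
* ``random`` — naive-library controls: C at 1 and 12, ten internal
  positions uniform i.i.d.

Identical spec + seed reproduces the panel byte-for-byte. Printed
fixture peptides from the source study (P1-P6, vasopressin and its
single-Cys variants) ship in :data:`FIXTURES`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import AMINO_ACIDS, Peptide

FAMILIES = ("str_like", "hpq_like", "random")

# In-text fixture peptides. P1 is printed two ways in the source study
# (running text vs table); both variants are kept, flagged by id.
FIXTURES: dict[str, str] = {
    "P1_table": "CTTRRPYLVCWL",
    "P1_text": "CTTEEPYLVCWL",
    "P2": "CGGSGGC",
    "P3": "CGSGGSGC",
    "P4": "CQPHPGQTC",
    "P5": "CPEGYILDDGFCTDIDE",
    "P6": "CYKLAEGDKYYIC",
    "vasopressin": "CYFQNCPRG",
    "pep1": "CYFQNSPRG",
    "pep2": "SYFQNCPRG",
}


def fixture_panel() -> list[Peptide]:
    """The bundled printed peptides as a panel (family ``fixture``)."""
    return [Peptide(id=k, residues=v, family="fixture") for k, v in FIXTURES.items()]


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for one synthetic panel.

    ``alphabet`` is the residue set for randomized X positions; cysteine
    is included by default ("any natural amino acid"), and can be
    excluded for selections that disfavor extra thiols.
    ``motif_offset`` fixes the HPQ/HPM start position (1-based) for
    hpq_like panels; ``None`` draws it uniformly from the internal range.
    """

    family: str
    n: int
    length: int = 12
    seed: int = 0
    alphabet: str = AMINO_ACIDS
    motif_offset: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.n < 1:
            raise ValueError("panel size n must be >= 1")
        bad = set(self.alphabet) - set(AMINO_ACIDS)
        if bad or not self.alphabet:
            raise ValueError(f"alphabet must be a nonempty subset of the 20 AAs: {bad}")


def _draw(rng: np.random.Generator, alphabet: str, k: int) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=k)]


def generate_str_like(spec: PanelSpec) -> list[Peptide]:
    """Panel matching the cyclization-selection consensus CPXNXXXPXXXC."""
    if spec.length != 12:
        raise ValueError("str_like panels are defined on the 12-mer scaffold")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    fixed = {0: "C", 1: "P", 3: "N", 7: "P", 11: "C"}
    panel = []
    for k in range(spec.n):
        letters = _draw(rng, spec.alphabet, 12)
        for pos, res in fixed.items():
            letters[pos] = res
        panel.append(
            Peptide(id=f"str_like_{k + 1:03d}", residues="".join(letters),
                    family="str_like")
        )
    return panel


def generate_hpq_like(spec: PanelSpec) -> list[Peptide]:
    """CX10C panel with an embedded HPQ or HPM motif at an internal offset."""
    if spec.length != 12:
        raise ValueError("hpq_like panels are defined on the 12-mer scaffold")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    panel = []
    for k in range(spec.n):
        letters = _draw(rng, spec.alphabet, 12)
        letters[0] = letters[11] = "C"
        motif = "HPQ" if rng.integers(0, 2) == 0 else "HPM"
        if spec.motif_offset is None:
            start = int(rng.integers(2, 10))  # 1-based offsets 2..9 keep C1/C12
        else:
            start = spec.motif_offset
            if not 2 <= start <= 9:
                raise ValueError("motif_offset must lie in 2..9 (internal positions)")
        letters[start - 1 : start + 2] = list(motif)
        panel.append(
            Peptide(id=f"hpq_like_{k + 1:03d}", residues="".join(letters),
                    family="hpq_like")
        )
    return panel


def generate_random_panel(spec: PanelSpec) -> list[Peptide]:
    """Uniform-random CX10C control panel."""
    if spec.length != 12:
        raise ValueError("random panels are defined on the 12-mer scaffold")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    panel = []
    for k in range(spec.n):
        letters = _draw(rng, spec.alphabet, 12)
        letters[0] = letters[11] = "C"
        panel.append(
            Peptide(id=f"random_{k + 1:03d}", residues="".join(letters),
                    family="random")
        )
    return panel


_GENERATORS = {
    "str_like": generate_str_like,
    "hpq_like": generate_hpq_like,
    "random": generate_random_panel,
}


def generate_panel(spec: PanelSpec) -> list[Peptide]:
    """Dispatch to the family's generator."""
    return _GENERATORS[spec.family](spec)


def write_fasta(panel: list[Peptide], path) -> None:
    """Write a panel as single-line FASTA; the description carries the family."""
    records = [
        SeqRecord(
            Seq(p.residues),
            id=p.id,
            description=f"family={p.family}" if p.family else "",
        )
        for p in panel
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line")


def read_fasta(path) -> list[Peptide]:
    """Read a peptide panel from FASTA.

    Sequences must use the 20-letter amino-acid alphabet; a
    ``family=...`` tag in the description is restored. An empty file
    yields an empty panel with a warning.
    """
    panel = []
    for record in SeqIO.parse(str(path), "fasta"):
        family = None
        for token in record.description.split():
            if token.startswith("family="):
                family = token.removeprefix("family=")
                if family == "None":
                    family = None
        try:
            panel.append(Peptide(id=record.id, residues=str(record.seq), family=family))
        except ValueError as exc:
            raise ValueError(f"FASTA record {record.id!r}: {exc}") from exc
    if not panel:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return panel
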
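"""Peptide sequences and their molecular representation.

One-letter peptide sequences are assembled into linear peptide molecules
(free amine N-terminus, free acid C-terminus, amide backbone, neutral
protonation) by concatenating per-residue SMILES units. The resulting
:class:`Molecule` wraps an RDKit mol and is the representation consumed by
the fingerprint module.

Conventions
-----------
* L-alpha stereocenters are written into the generated SMILES; the
  fingerprint module strips stereo descriptors by default.
* Cysteines are free thiols: no disulfide bonds and no cyclization linker
  are represented.
* Neutral protonation throughout (no zwitterions), so molecular formulas
  are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Internal-residue SMILES units. Concatenating units forms the amide
# backbone; appending "O" to the last unit closes the C-terminal acid, so
# the free amino acid is always ``unit + "O"``. Alpha carbons carry the
# L configuration ((S) by CIP for all residues except cysteine, where the
# sulfur flips the priority to (R)); Ile is (2S,3S) and Thr (2S,3R).
_INTERNAL_SMILES = {
    "A": "N[C@@H](C)C(=O)",
    "R": "N[C@@H](CCCNC(=N)N)C(=O)",
    "N": "N[C@@H](CC(N)=O)C(=O)",
    "D": "N[C@@H](CC(O)=O)C(=O)",
    "C": "N[C@@H](CS)C(=O)",
    "E": "N[C@@H](CCC(O)=O)C(=O)",
    "Q": "N[C@@H](CCC(N)=O)C(=O)",
    "G": "NCC(=O)",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)",
    "I": "N[C@@H]([C@@H](C)CC)C(=O)",
    "L": "N[C@@H](CC(C)C)C(=O)",
    "K": "N[C@@H](CCCCN)C(=O)",
    "M": "N[C@@H](CCSC)C(=O)",
    "F": "N[C@@H](Cc1ccccc1)C(=O)",
    "P": "N1CCC[C@H]1C(=O)",
    "S": "N[C@@H](CO)C(=O)",
    "T": "N[C@@H]([C@H](O)C)C(=O)",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
    "V": "N[C@@H](C(C)C)C(=O)",
}

_WATER = Counter({"H": 2, "O": 1})


class UnsupportedResidueError(ValueError):
    """A residue letter outside the 20 canonical amino acids."""


class SmilesParseError(ValueError):
    """Malformed SMILES input."""


@dataclass(frozen=True)
class Peptide:
    """A peptide as an identifier plus one-letter residue string.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"P2"`` or ``"str_like_003"``.
    residues : str
        Uppercase one-letter codes over the 20-residue alphabet.
    family : str, optional
        Panel label: ``"str_like"``, ``"hpq_like"``, ``"random"`` or
        ``"fixture"``.
    """

    id: str
    residues: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"peptide {self.id!r}: empty residue string")
        object.__setattr__(self, "residues", self.residues.upper())
        for letter in self.residues:
            if letter not in AMINO_ACIDS:
                raise UnsupportedResidueError(
                    f"peptide {self.id!r}: residue {letter!r} is not one of "
                    f"the 20 natural amino acids"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ResidueFragment:
    """SMILES fragment of one amino acid (internal or free form)."""

    code: str
    form: str  # "internal" | "free"
    smiles: str
    formula: dict = field(compare=False)


@dataclass(frozen=True)
class Molecule:
    """Heavy-atom chemical graph with a canonical SMILES serialization."""

    rdmol: Chem.Mol = field(compare=False, repr=False)
    smiles: str

    @property
    def atoms(self) -> list[tuple[str, int, bool]]:
        """(element, formal charge, aromatic flag) per heavy atom."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        """(begin index, end index, bond order) per bond."""
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return mol


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    The stored serialization is RDKit-canonical, so parsing a molecule's
    own ``smiles`` round-trips to an identical string.
    """
    mol = _mol_from_smiles(smiles)
    return Molecule(rdmol=mol, smiles=Chem.MolToSmiles(mol))


def molecular_formula(molecule: Molecule) -> dict[str, int]:
    """Element counts including implicit hydrogens.

    Hydrogen counts come from RDKit valence rules, so the formula of an
    assembled peptide can be checked against free-residue element
    arithmetic.
    """
    counts: Counter[str] = Counter()
    for atom in molecule.rdmol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    return {el: n for el, n in counts.items() if n}


def residue_smiles(code: str, form: str = "internal") -> ResidueFragment:
    """Return the SMILES fragment for one amino acid.

    ``form="free"`` is the intact neutral amino acid; ``form="internal"``
    is the chain unit with open backbone attachment points (the free
    residue minus one water).
    """
    code = code.upper()
    if code not in _INTERNAL_SMILES:
        raise UnsupportedResidueError(
            f"residue {code!r} is not one of the 20 natural amino acids"
        )
    if form not in ("internal", "free"):
        raise ValueError(f"form must be 'internal' or 'free', got {form!r}")
    unit = _INTERNAL_SMILES[code]
    free_smiles = Chem.MolToSmiles(_mol_from_smiles(unit + "O"))
    free_formula = Counter(molecular_formula(parse_smiles(free_smiles)))
    if form == "free":
        return ResidueFragment(code, "free", free_smiles, dict(free_formula))
    internal_formula = free_formula - _WATER
    return ResidueFragment(code, "internal", unit, dict(internal_formula))


def free_residue_molecule(code: str) -> Molecule:
    """The free (uncondensed) amino acid as a molecule."""
    return parse_smiles(residue_smiles(code, form="free").smiles)


def assemble_peptide(peptide: Peptide | str) -> Molecule:
    """Assemble a linear peptide molecule from its sequence.

    Consecutive residues are joined by amide bonds; the N-terminus is a
    free amine and the C-terminus a free carboxylic acid. The molecular
    formula equals the sum of free-residue formulas minus (L-1) waters.
    """
    if isinstance(peptide, str):
        peptide = Peptide(id=peptide, residues=peptide)
    try:
        smiles = "".join(_INTERNAL_SMILES[c] for c in peptide.residues) + "O"
    except KeyError as exc:  # Peptide validation normally catches this first
        raise UnsupportedResidueError(
            f"peptide {peptide.id!r}: unsupported residue {exc.args[0]!r}"
        ) from exc
    try:
        return parse_smiles(smiles)
    except SmilesParseError as exc:
        raise SmilesParseError(
            f"assembly failed for peptide {peptide.id!r}: {exc}"
        ) from exc
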
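"""MinHashed atom-pair fingerprints.

A molecule is represented by its *shingle set*: for every unordered pair
of distinct, connected heavy atoms (i, j) and every radius k = 1..max_radius,
one string ``envA|d|envB`` where envA and envB are the canonical SMILES of
the circular substructures of radius k around the two atoms (ordered
lexicographically) and d is their topological distance in bonds. The
Jaccard similarity between two shingle sets is estimated by MinHash:
component i of a signature is the minimum, over the set, of an affine
64-bit hash salted by permutation index i; the fraction of equal
components between two signatures estimates |A ∩ B| / |A ∪ B|.

Hash contract (cross-platform deterministic, no C extensions):

* base hash: first 8 bytes of BLAKE2b(shingle UTF-8), little-endian uint64;
* permutation i: ``(a_i * h + b_i) mod 2**64`` with odd multiplier ``a_i``,
  both parameters drawn from ``numpy.random.Generator(PCG64(seed))``.

``exact_jaccard`` is the brute-force oracle the estimator is validated
against.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem

from .chem import Molecule

__all__ = [
    "FingerprintParams",
    "MinHashSignature",
    "topological_distances",
    "atom_environment",
    "shingle_set",
    "minhash",
    "estimate_jaccard",
    "exact_jaccard",
]

UNREACHABLE = -1
_HASH_CHUNK = 512  # shingles hashed per vectorized block, caps memory


@dataclass(frozen=True)
class FingerprintParams:
    """Parameters of the fingerprint.

    max_radius : circular-environment radius in bonds (default 2).
    signature_length : number of MinHash permutations (default 1024).
    seed : integer salt for the hash family; fixed seed means fully
        deterministic signatures.
    include_stereo : keep stereo descriptors in environment SMILES
        (default off, for canonicalization-stable environments).
    """

    max_radius: int = 2
    signature_length: int = 1024
    seed: int = 42
    include_stereo: bool = False

    def __post_init__(self) -> None:
        if self.max_radius < 1:
            raise ValueError("max_radius must be >= 1")
        if self.signature_length < 16:
            raise ValueError("signature_length must be >= 16")


@dataclass(frozen=True)
class MinHashSignature:
    """Fixed-length vector of per-permutation hash minima."""

    components: np.ndarray  # uint64, length = params.signature_length
    params: FingerprintParams

    def __post_init__(self) -> None:
        comps = np.ascontiguousarray(self.components, dtype=np.uint64)
        comps.setflags(write=False)
        object.__setattr__(self, "components", comps)
        if comps.shape != (self.params.signature_length,):
            raise ValueError(
                f"signature has {comps.size} components, params declare "
                f"{self.params.signature_length}"
            )

    def to_json(self) -> str:
        rec = {
            "params": {
                "max_radius": self.params.max_radius,
                "signature_length": self.params.signature_length,
                "seed": self.params.seed,
                "include_stereo": self.params.include_stereo,
            },
            "components": [int(c) for c in self.components],
        }
        return json.dumps(rec)

    @classmethod
    def from_json(cls, text: str) -> "MinHashSignature":
        rec = json.loads(text)
        return cls(
            components=np.array(rec["components"], dtype=np.uint64),
            params=FingerprintParams(**rec["params"]),
        )


def topological_distances(molecule: Molecule) -> np.ndarray:
    """All-pairs shortest-path bond counts.

    Returns an integer matrix with zero diagonal; pairs in different
    connected components get the sentinel :data:`UNREACHABLE`.
    """
    dmat = Chem.GetDistanceMatrix(molecule.rdmol)
    n = molecule.num_atoms
    out = np.full((n, n), UNREACHABLE, dtype=np.int64)
    reachable = dmat < n  # RDKit marks unreachable pairs with a huge float
    out[reachable] = dmat[reachable].astype(np.int64)
    return out


def atom_environment(
    molecule: Molecule,
    atom_index: int,
    radius: int,
    include_stereo: bool = False,
) -> str:
    """Canonical SMILES of the circular substructure around one atom.

    The substructure is the subgraph induced by all atoms within
    ``radius`` bonds of ``atom_index``, serialized canonically and rooted
    at the central atom, so symmetry-equivalent atoms yield identical
    strings. A radius beyond the molecule's diameter simply saturates at
    the whole connected component.
    """
    mol = molecule.rdmol
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        atoms = [atom_index]
    else:
        env_bonds = Chem.FindAtomEnvironmentOfRadiusN(
            mol, radius, atom_index, useHs=False, enforceSize=False
        )
        seen = {atom_index}
        for bond_idx in env_bonds:
            bond = mol.GetBondWithIdx(bond_idx)
            seen.add(bond.GetBeginAtomIdx())
            seen.add(bond.GetEndAtomIdx())
        atoms = sorted(seen)
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=atoms,
        rootedAtAtom=atom_index,
        canonical=True,
        isomericSmiles=include_stereo,
    )


def shingle_set(
    molecule: Molecule, params: FingerprintParams | None = None
) -> frozenset[str]:
    """Atom-pair shingles of a molecule.

    One shingle per unordered pair of distinct connected heavy atoms and
    per radius 1..max_radius; self-pairs are excluded and pairs spanning
    disconnected fragments skipped. Returns a set (duplicates collapse).
    """
    params = params or FingerprintParams()
    mol = molecule.rdmol
    n = mol.GetNumAtoms()
    if n < 2:
        warnings.warn(
            "molecule has fewer than 2 heavy atoms: empty shingle set",
            stacklevel=2,
        )
        return frozenset()
    dist = topological_distances(molecule)
    envs = [
        [
            atom_environment(molecule, i, r, params.include_stereo)
            for i in range(n)
        ]
        for r in range(1, params.max_radius + 1)
    ]
    shingles: set[str] = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if d == UNREACHABLE:
                continue
            for r_envs in envs:
                a, b = r_envs[i], r_envs[j]
                if b < a:
                    a, b = b, a
                shingles.add(f"{a}|{d}|{b}")
    return frozenset(shingles)


def _base_hashes(shingles: list[str]) -> np.ndarray:
    out = np.empty(len(shingles), dtype=np.uint64)
    for k, s in enumerate(shingles):
        digest = hashlib.blake2b(s.encode("utf-8"), digest_size=8).digest()
        out[k] = int.from_bytes(digest, "little")
    return out


def _permutation_params(params: FingerprintParams) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.Generator(np.random.PCG64(params.seed))
    a = rng.integers(0, 2**64, size=params.signature_length, dtype=np.uint64)
    a |= np.uint64(1)  # odd multiplier: x -> a*x + b is a bijection mod 2^64
    b = rng.integers(0, 2**64, size=params.signature_length, dtype=np.uint64)
    return a, b


def minhash(
    shingles: frozenset[str] | set[str], params: FingerprintParams | None = None
) -> MinHashSignature:
    """MinHash signature of a shingle set.

    Deterministic for a given (set, params): component i is the minimum
    of the i-th salted hash over all shingles.
    """
    params = params or FingerprintParams()
    if not shingles:
        raise ValueError("cannot MinHash an empty shingle set")
    ordered = sorted(shingles)
    a, b = _permutation_params(params)
    mins = np.full(params.signature_length, np.iinfo(np.uint64).max, dtype=np.uint64)
    with np.errstate(over="ignore"):  # mod-2^64 wraparound is the hash map
        for start in range(0, len(ordered), _HASH_CHUNK):
            h = _base_hashes(ordered[start : start + _HASH_CHUNK])
            block = a[:, None] * h[None, :] + b[:, None]
            np.minimum(mins, block.min(axis=1), out=mins)
    return MinHashSignature(components=mins, params=params)


def estimate_jaccard(a: MinHashSignature, b: MinHashSignature) -> float:
    """Estimated Jaccard similarity: fraction of equal signature components."""
    if a.params != b.params:
        raise ValueError(
            f"signatures built with different params are incomparable: "
            f"{a.params} vs {b.params}"
        )
    return float(np.mean(a.components == b.components))


def exact_jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Exact Jaccard similarity |a ∩ b| / |a ∪ b| of two shingle sets."""
    if not a and not b:
        raise ValueError("Jaccard similarity of two empty sets is undefined")
    union = len(a | b)
    return len(a & b) / union


def strip_stereo(molecule: Molecule) -> Molecule:
    """Copy of a molecule with stereo descriptors removed."""
    mol = Chem.Mol(molecule.rdmol)
    Chem.RemoveStereochemistry(mol)
    return Molecule(rdmol=mol, smiles=Chem.MolToSmiles(mol))


def with_signature_length(
    params: FingerprintParams, signature_length: int
) -> FingerprintParams:
    """Convenience: same params at a different signature length."""
    return replace(params, signature_length=signature_length)
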
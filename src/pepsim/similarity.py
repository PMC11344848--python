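"""The three similarity methods and cross-family averaging.

Methods
-------
full_map4
    Assemble each whole peptide into a molecule, fingerprint it, and
    report the estimated Jaccard similarity between MinHash signatures
    (equivalently 1 minus the Jaccard distance: 1 for identical, 0 for
    highly dissimilar).
positional_mean
    Decompose similarity by aligned position: at each position the two
    residues are compared as free amino-acid molecules via the same
    fingerprint route; identical residues short-circuit to exactly 1.
    The scalar matrix entry is the arithmetic mean over positions (the
    per-position profile is the primary output; the mean is a
    convenience).
tfidf_cosine
    Treat each sequence as a bag of residue letters, weight counts by
    smoothed inverse document frequency idf(t) = ln((1+N)/(1+df(t))) + 1
    over the supplied panel as corpus, L2-normalize, and take cosines.

Cross-family averaging reports, per peptide, its mean similarity to the
other family and to its own family, always excluding self-comparisons.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .chem import AMINO_ACIDS, Peptide, assemble_peptide, free_residue_molecule
from .fingerprints import (
    FingerprintParams,
    MinHashSignature,
    estimate_jaccard,
    exact_jaccard,
    minhash,
    shingle_set,
)

METHODS = ("full_map4", "positional_mean", "tfidf_cosine")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Labelled symmetric matrix of similarities in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass(frozen=True)
class PositionalProfile:
    """Per-position similarity between two equal-length peptides."""

    pair: tuple[str, str]
    values: np.ndarray  # length L, 1-based positions 1..L

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class PanelComparison:
    """Per-peptide cross-group and within-group mean similarities.

    ``within_mean`` is ``None`` for a singleton group (the mean over an
    empty set is undefined, not zero). Self-comparisons never enter any
    mean.
    """

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    cross_mean: dict[str, float]
    within_mean: dict[str, float | None]
    method: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "group_a": list(self.group_a),
                "group_b": list(self.group_b),
                "cross_mean": self.cross_mean,
                "within_mean": self.within_mean,
            },
            indent=2,
            sort_keys=True,
        )


@lru_cache(maxsize=4096)
def _sequence_signature(residues: str, params: FingerprintParams) -> MinHashSignature:
    return minhash(shingle_set(assemble_peptide(residues), params), params)


@lru_cache(maxsize=4096)
def _sequence_shingles(residues: str, params: FingerprintParams) -> frozenset[str]:
    return shingle_set(assemble_peptide(residues), params)


@lru_cache(maxsize=256)
def _residue_signature(code: str, params: FingerprintParams) -> MinHashSignature:
    return minhash(shingle_set(free_residue_molecule(code), params), params)


@lru_cache(maxsize=256)
def _residue_shingles(code: str, params: FingerprintParams) -> frozenset[str]:
    return shingle_set(free_residue_molecule(code), params)


def full_similarity(
    a: Peptide | str,
    b: Peptide | str,
    params: FingerprintParams | None = None,
    exact: bool = False,
) -> float:
    """Whole-sequence fingerprint similarity of two peptides.

    With ``exact=True`` the Jaccard similarity is computed directly on
    the shingle sets (the brute-force route) instead of estimated from
    MinHash signatures.
    """
    params = params or FingerprintParams()
    ra = a.residues if isinstance(a, Peptide) else a
    rb = b.residues if isinstance(b, Peptide) else b
    if exact:
        return exact_jaccard(_sequence_shingles(ra, params), _sequence_shingles(rb, params))
    return estimate_jaccard(
        _sequence_signature(ra, params), _sequence_signature(rb, params)
    )


def positional_similarity(
    a: Peptide | str,
    b: Peptide | str,
    params: FingerprintParams | None = None,
    exact: bool = False,
) -> PositionalProfile:
    """Per-position fingerprint similarity of two aligned peptides.

    Each position contributes the Jaccard similarity between the free
    amino-acid molecules of the two residues there; positions with
    identical residues are exactly 1.
    """
    params = params or FingerprintParams()
    pa = a if isinstance(a, Peptide) else Peptide(id=a, residues=a)
    pb = b if isinstance(b, Peptide) else Peptide(id=b, residues=b)
    if len(pa) != len(pb):
        raise ValueError(
            f"positional similarity needs equal lengths: "
            f"{pa.id!r} has {len(pa)}, {pb.id!r} has {len(pb)}"
        )
    values = np.empty(len(pa))
    for p, (ra, rb) in enumerate(zip(pa.residues, pb.residues)):
        if ra == rb:
            values[p] = 1.0
        elif exact:
            values[p] = exact_jaccard(
                _residue_shingles(ra, params), _residue_shingles(rb, params)
            )
        else:
            values[p] = estimate_jaccard(
                _residue_signature(ra, params), _residue_signature(rb, params)
            )
    return PositionalProfile(pair=(pa.id, pb.id), values=values)


def _tfidf_vectors(panel: list[Peptide]) -> np.ndarray:
    """Rows: L2-normalized tf-idf vectors over the 20-letter alphabet."""
    n = len(panel)
    counts = np.zeros((n, len(AMINO_ACIDS)), dtype=float)
    index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    for row, pep in enumerate(panel):
        for letter, c in Counter(pep.residues).items():
            counts[row, index[letter]] = c
    df = (counts > 0).sum(axis=0)
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    weighted = counts * idf
    norms = np.linalg.norm(weighted, axis=1)
    return weighted / norms[:, None]


def tfidf_cosine(panel: list[Peptide]) -> SimilarityMatrix:
    """Pairwise cosine similarity of idf-weighted residue-count vectors.

    The idf corpus is exactly the supplied panel, mirroring a joint
    comparison of all families in one run.
    """
    if not panel:
        raise ValueError("tfidf_cosine needs a nonempty panel")
    _check_unique_ids(panel)
    vectors = _tfidf_vectors(panel)
    values = np.clip(vectors @ vectors.T, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(
        labels=tuple(p.id for p in panel), values=values, method="tfidf_cosine"
    )


def _check_unique_ids(panel: list[Peptide]) -> None:
    ids = [p.id for p in panel]
    dupes = [i for i, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate peptide ids in panel: {dupes}")


def pairwise_matrix(
    panel: list[Peptide],
    method: str = "full_map4",
    params: FingerprintParams | None = None,
    exact: bool = False,
) -> SimilarityMatrix:
    """Symmetric similarity matrix over a panel for one method."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if len(panel) < 2:
        raise ValueError("pairwise_matrix needs a panel of at least 2 peptides")
    _check_unique_ids(panel)
    if method == "tfidf_cosine":
        return tfidf_cosine(panel)
    params = params or FingerprintParams()
    n = len(panel)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if method == "full_map4":
                s = full_similarity(panel[i], panel[j], params, exact=exact)
            else:
                s = positional_similarity(panel[i], panel[j], params, exact=exact).mean()
            values[i, j] = values[j, i] = s
    if method == "positional_mean":
        # diagonal of a self-comparison profile is all ones
        np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        labels=tuple(p.id for p in panel), values=values, method=method
    )


def cross_family_averages(
    matrix: SimilarityMatrix,
    group_a: list[str] | tuple[str, ...],
    group_b: list[str] | tuple[str, ...],
) -> PanelComparison:
    """Per-peptide mean similarity to the other group and to its own.

    Groups must be disjoint subsets of the matrix labels. The diagonal
    (self-similarity) never contributes; a singleton group's within-group
    mean is undefined and reported as ``None``.
    """
    ga, gb = tuple(group_a), tuple(group_b)
    label_set = set(matrix.labels)
    missing = (set(ga) | set(gb)) - label_set
    if missing:
        raise ValueError(f"group ids absent from matrix: {sorted(missing)}")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    cross: dict[str, float] = {}
    within: dict[str, float | None] = {}
    for own, other in ((ga, gb), (gb, ga)):
        for pid in own:
            cross[pid] = float(
                np.mean([matrix.loc(pid, q) for q in other])
            )
            mates = [q for q in own if q != pid]
            within[pid] = (
                float(np.mean([matrix.loc(pid, q) for q in mates]))
                if mates
                else None
            )
    return PanelComparison(
        group_a=ga, group_b=gb, cross_mean=cross, within_mean=within,
        method=matrix.method,
    )


def manual_tfidf_cosine(seq_a: str, seq_b: str, corpus: list[str]) -> float:
    """Direct-arithmetic cosine for one pair given an explicit corpus.

    Exists as a readable reference formula; `tfidf_cosine` is the
    vectorized panel version.
    """
    n = len(corpus)
    letters = sorted(set("".join(corpus)))
    df = {t: sum(t in s for s in corpus) for t in letters}
    idf = {t: math.log((1 + n) / (1 + df[t])) + 1.0 for t in letters}

    def vec(seq: str) -> np.ndarray:
        c = Counter(seq)
        v = np.array([c.get(t, 0) * idf[t] for t in letters], dtype=float)
        return v / np.linalg.norm(v)

    return float(vec(seq_a) @ vec(seq_b))
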
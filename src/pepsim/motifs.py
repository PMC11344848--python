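"""Motif scanning, deduplication, and position-frequency / logo analytics.

Patterns are strings over the 20 amino-acid letters plus the wildcard X.
Match offsets are 1-based inclusive, the convention of the peptide
literature. The two canonical linear streptavidin-binding motifs HPQ and
HPM are scanned separately and reported jointly by :func:`scan_hpq`;
the cyclization-selected consensus is ``CPXNXXXPXXXC`` (fixed C1, P2,
N4, P8, C12 on a 12-mer scaffold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem import AMINO_ACIDS, Peptide

HPQ_PATTERNS = ("HPQ", "HPM")
STR_CONSENSUS = "CPXNXXXPXXXC"

_PATTERN_ALPHABET = set(AMINO_ACIDS) | {"X"}


def _residues(seq: Peptide | str) -> str:
    return seq.residues if isinstance(seq, Peptide) else seq.upper()


def _check_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern:
        raise ValueError("empty motif pattern")
    bad = set(pattern) - _PATTERN_ALPHABET
    if bad:
        raise ValueError(f"pattern letters outside 20-AA alphabet + X: {sorted(bad)}")
    return pattern


def scan_motif(seq: Peptide | str, pattern: str) -> list[int]:
    """All 1-based offsets where ``pattern`` matches, overlaps included.

    X matches any residue; a fixed letter must match exactly. A pattern
    longer than the sequence yields an empty list.
    """
    residues = _residues(seq)
    pattern = _check_pattern(pattern)
    hits = []
    for start in range(len(residues) - len(pattern) + 1):
        if all(
            p == "X" or p == residues[start + k]
            for k, p in enumerate(pattern)
        ):
            hits.append(start + 1)
    return hits


def scan_hpq(seq: Peptide | str) -> list[int]:
    """Joint 1-based offsets of the HPQ and HPM streptavidin motifs."""
    return sorted(set(scan_motif(seq, "HPQ")) | set(scan_motif(seq, "HPM")))


def matches_consensus(seq: Peptide | str) -> bool:
    """True iff the sequence is a 12-mer matching CPXNXXXPXXXC at offset 1."""
    residues = _residues(seq)
    return len(residues) == 12 and scan_motif(residues, STR_CONSENSUS) == [1]


def unique_sequences(panel: list[Peptide]) -> tuple[list[Peptide], int]:
    """Deduplicate a panel by residue string, keeping first occurrences."""
    seen: set[str] = set()
    kept: list[Peptide] = []
    for pep in panel:
        if pep.residues not in seen:
            seen.add(pep.residues)
            kept.append(pep)
    return kept, len(kept)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position residue counts over an aligned panel.

    ``counts`` has shape (length, 20) with columns ordered by
    :data:`pepsim.chem.AMINO_ACIDS`; every row sums to ``n_sequences``.
    """

    counts: np.ndarray
    n_sequences: int
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != len(self.alphabet):
            raise ValueError("counts must have one column per alphabet letter")
        if not (counts.sum(axis=1) == self.n_sequences).all():
            raise ValueError("every position's counts must sum to n_sequences")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences


def build_pfm(panel: list[Peptide]) -> PositionFrequencyMatrix:
    """Tally residue counts per position over equal-length sequences."""
    if not panel:
        raise ValueError("cannot build a PFM from an empty panel")
    length = len(panel[0])
    offenders = [p.id for p in panel if len(p) != length]
    if offenders:
        raise ValueError(
            f"sequences of unequal length (expected {length}): {offenders}"
        )
    index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((length, len(AMINO_ACIDS)), dtype=np.int64)
    for pep in panel:
        for pos, letter in enumerate(pep.residues):
            counts[pos, index[letter]] += 1
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(panel))


def information_content(
    pfm: PositionFrequencyMatrix, small_sample_correction: bool = False
) -> np.ndarray:
    """Per-position information content in bits.

    IC(p) = log2(20) - H(p), where H is the Shannon entropy of the
    position's residue frequencies. A fully conserved position scores
    log2(20) ~ 4.32 bits, a uniform position 0. The optional
    small-sample correction subtracts e_n = (|alphabet|-1) / (2 ln 2 n),
    clipped at zero, as sequence-logo software does for small panels.
    """
    freqs = pfm.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = math.log2(len(pfm.alphabet)) - entropy
    if small_sample_correction:
        e_n = (len(pfm.alphabet) - 1) / (2 * math.log(2) * pfm.n_sequences)
        ic = np.clip(ic - e_n, 0.0, None)
    return ic


def consensus_string(
    pfm: PositionFrequencyMatrix, threshold: float = 0.9
) -> str:
    """Threshold consensus: the residue reaching ``threshold`` frequency, else X.

    ``threshold`` must exceed 0.5 so at most one residue can qualify per
    position.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1.0] for a unique winner")
    freqs = pfm.frequencies()
    out = []
    for pos in range(pfm.length):
        winner = int(np.argmax(freqs[pos]))
        out.append(pfm.alphabet[winner] if freqs[pos, winner] >= threshold else "X")
    return "".join(out)
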
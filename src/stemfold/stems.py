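"""Candidate stem enumeration.

An RNA secondary structure is built from *stems* (helices): runs of
consecutive base pairs between two antiparallel segments of the chain.
This module constructs the matrix of allowed base pairs for a sequence
(Watson-Crick A-U and G-C plus the G-U wobble), exhaustively enumerates
every candidate stem -- including all sub-stems of longer runs -- and
classifies pairwise stem relations (pseudoknot crossing, base-sharing
overlap) needed to build the selection Hamiltonian.

Coordinates are 0-based throughout; only text output formats use 1-based
indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "ALLOWED_PAIRS",
    "PairMatrix",
    "Stem",
    "StemSet",
    "clean_sequence",
    "build_pair_matrix",
    "enumerate_stems",
    "is_pseudoknot",
    "is_overlap",
]

#: Allowed base pairs: Watson-Crick plus the G-U wobble, order-insensitive.
ALLOWED_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

_ALPHABET = frozenset("ACGU")


def clean_sequence(sequence: str) -> str:
    """Normalize an RNA sequence: upper-case, T -> U, validate alphabet.

    Raises
    ------
    ValueError
        If the sequence is empty or contains symbols outside A/C/G/U
        (ambiguity codes are rejected).
    """
    seq = sequence.strip().upper().replace("T", "U")
    if not seq:
        raise ValueError("empty RNA sequence")
    bad = sorted(set(seq) - _ALPHABET)
    if bad:
        raise ValueError(
            f"invalid symbols {bad} in RNA sequence; expected only A/C/G/U "
            "(T is accepted and read as U; ambiguity codes are not supported)"
        )
    return seq


@dataclass(frozen=True)
class PairMatrix:
    """Strictly upper-triangular boolean matrix of allowed base pairs.

    ``entries[p, q]`` is true iff ``p < q`` and bases p and q may pair.
    """

    n: int
    entries: np.ndarray = field(repr=False)

    def can_pair(self, p: int, q: int) -> bool:
        if not (0 <= p < q < self.n):
            return False
        return bool(self.entries[p, q])


@dataclass(frozen=True, order=True)
class Stem:
    """A run of ``k`` consecutive base pairs ``(i+t, j-t)``, t = 0..k-1.

    ``i`` indexes the first base of the 5' strand, ``j`` the last base of
    the 3' strand. The innermost pair encloses ``j - i + 1 - 2k`` unpaired
    bases.
    """

    i: int
    j: int
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"stem length must be >= 1, got {self.k}")
        if self.i < 0 or self.j <= self.i:
            raise ValueError(f"invalid stem coordinates ({self.i}, {self.j})")
        if self.loop_size < 0:
            raise ValueError(
                f"stem ({self.i}, {self.j}, {self.k}) strands cross: "
                f"enclosed loop size {self.loop_size} < 0"
            )

    @property
    def loop_size(self) -> int:
        return self.j - self.i + 1 - 2 * self.k

    def pairs(self) -> tuple[tuple[int, int], ...]:
        """Base pairs of this stem as (p, q) tuples with p < q."""
        return tuple((self.i + t, self.j - t) for t in range(self.k))

    def base_indices(self) -> frozenset[int]:
        """All sequence positions used by this stem's pairs."""
        return frozenset(range(self.i, self.i + self.k)) | frozenset(
            range(self.j - self.k + 1, self.j + 1)
        )


@dataclass(frozen=True)
class StemSet:
    """The ordered candidate set M = {m_0, ..., m_{N-1}} for a sequence.

    Ordering is by (i, j, k) ascending, which fixes the variable indexing
    of the downstream binary quadratic model and makes runs reproducible.
    """

    sequence: str
    stems: tuple[Stem, ...]
    min_stem: int
    min_loop: int

    def __len__(self) -> int:
        return len(self.stems)

    def __iter__(self) -> Iterator[Stem]:
        return iter(self.stems)

    def __getitem__(self, idx: int) -> Stem:
        return self.stems[idx]

    def index(self, stem: Stem) -> int:
        return self.stems.index(stem)

    def to_table(self) -> str:
        """Tabular text listing: index, i, j, k plus 1-based display coords."""
        lines = ["index\ti\tj\tk\tfirst_1based\tlast_1based"]
        for idx, s in enumerate(self.stems):
            lines.append(f"{idx}\t{s.i}\t{s.j}\t{s.k}\t{s.i + 1}\t{s.j + 1}")
        return "\n".join(lines) + "\n"


def build_pair_matrix(sequence: str) -> PairMatrix:
    """Build the upper-triangular matrix of allowed base pairs.

    True exactly at (p, q), p < q, where bases p and q form a
    Watson-Crick (A-U, G-C) or wobble (G-U) pair.
    """
    seq = clean_sequence(sequence)
    n = len(seq)
    entries = np.zeros((n, n), dtype=bool)
    for p in range(n):
        for q in range(p + 1, n):
            if seq[p] + seq[q] in ALLOWED_PAIRS:
                entries[p, q] = True
    return PairMatrix(n=n, entries=entries)


def enumerate_stems(sequence: str, min_stem: int = 3, min_loop: int = 3) -> StemSet:
    """Exhaustively enumerate candidate stems, including all sub-stems.

    Scans the pair matrix along anti-diagonals for runs of consecutive
    pairs. Every (i, j, k) with ``k >= min_stem``, all k implied pairs
    allowed, and enclosed loop ``j - i + 1 - 2k >= min_loop`` is included;
    sub-stems of longer runs are therefore first-class candidates. Runs in
    O(n^2 * max run length).

    Parameters
    ----------
    min_stem : int
        Minimum number of consecutive pairs per stem (default 3: shorter
        helices are not considered stable).
    min_loop : int
        Minimum number of unpaired bases enclosed by the innermost pair
        (default 3: the backbone cannot turn more tightly).
    """
    if min_stem < 1:
        raise ValueError(f"min_stem must be >= 1, got {min_stem}")
    if min_loop < 0:
        raise ValueError(f"min_loop must be >= 0, got {min_loop}")
    matrix = build_pair_matrix(sequence)
    seq = clean_sequence(sequence)
    n = matrix.n
    entries = matrix.entries

    # run[p][q] = number of consecutive allowed pairs (p, q), (p+1, q-1), ...
    run = np.zeros((n, n), dtype=np.int64)
    for p in range(n - 1, -1, -1):
        for q in range(p + 1, n):
            if entries[p, q]:
                inner = run[p + 1, q - 1] if (p + 1 < q - 1) else 0
                run[p, q] = 1 + inner

    stems: list[Stem] = []
    for p in range(n):
        for q in range(p + 1, n):
            r = run[p, q]
            if r < min_stem:
                continue
            # loop constraint caps k from above: j - i + 1 - 2k >= min_loop
            k_cap = (q - p + 1 - min_loop) // 2
            for k in range(min_stem, min(r, k_cap) + 1):
                stems.append(Stem(i=p, j=q, k=k))
    stems.sort()
    return StemSet(sequence=seq, stems=tuple(stems), min_stem=min_stem, min_loop=min_loop)


def is_pseudoknot(a: Stem, b: Stem) -> bool:
    """True iff the two stems' outer coordinate intervals interleave.

    Crossing without overlap: i_a < i_b < j_a < j_b (or with a and b
    swapped). Symmetric in its arguments.
    """
    return (a.i < b.i < a.j < b.j) or (b.i < a.i < b.j < a.j)


def is_overlap(a: Stem, b: Stem) -> bool:
    """True iff the two stems share any base position.

    A base may take part in at most one pair, so any two stems whose base
    index sets intersect cannot be selected together (this also excludes
    base triplets). A stem always overlaps itself.
    """
    # Each stem occupies two intervals; test the four combinations.
    ivs_a = ((a.i, a.i + a.k - 1), (a.j - a.k + 1, a.j))
    ivs_b = ((b.i, b.i + b.k - 1), (b.j - b.k + 1, b.j))
    for lo_a, hi_a in ivs_a:
        for lo_b, hi_b in ivs_b:
            if lo_a <= hi_b and lo_b <= hi_a:
                return True
    return False
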
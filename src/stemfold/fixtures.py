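"""Synthetic sequences with planted structures.

Every stage of the pipeline is testable without downloads: this module
generates random RNA sequences with a controlled GC content, hairpins
whose two arms are exactly reverse-complementary, and H-type pseudoknots
with two planted crossing stems. Planted-stem arms are drawn from G/C
(hairpins) so the planted helix is the unique energy leader, and
generated sequences are rejection-sampled until the enumerated candidate
set contains no stem that competes with the planted ones -- which makes
recovery tests sharp rather than probabilistic.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import random

from .metrics import Structure
from .stems import Stem, enumerate_stems

__all__ = [
    "random_sequence",
    "planted_hairpin",
    "planted_pseudoknot",
    "reverse_complement",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_MAX_ATTEMPTS = 500


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (A<->U, G<->C)."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def random_sequence(length: int, gc_fraction: float = 0.5, seed: int | None = None) -> str:
    """Random RNA string; each position is G/C with probability gc_fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = random.Random(seed)
    out = []
    for _ in range(length):
        if rng.random() < gc_fraction:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AU"))
    return "".join(out)


def _stem_pairs(stem: Stem) -> frozenset[tuple[int, int]]:
    return frozenset(stem.pairs())


def _only_substems(sequence: str, planted: list[Stem], min_stem: int, min_loop: int) -> bool:
    """True iff every enumerated candidate's pairs lie within the planted pairs."""
    planted_pairs: set[tuple[int, int]] = set()
    for s in planted:
        planted_pairs |= set(s.pairs())
    candidates = enumerate_stems(sequence, min_stem=min_stem, min_loop=min_loop)
    found = {(s.i, s.j, s.k) for s in candidates}
    for s in planted:
        if (s.i, s.j, s.k) not in found:
            return False
    return all(set(s.pairs()) <= planted_pairs for s in candidates)


def planted_hairpin(
    stem_len: int, loop_len: int, seed: int | None = None
) -> tuple[str, Structure]:
    """A hairpin: G/C arm + all-A loop + reverse-complementary arm.

    Returns the sequence and the planted pair set
    {(t, n-1-t) : t < stem_len}. The loop is all-A, which cannot pair
    with the G/C arms, and arm draws are rejected until no stem outside
    the planted helix (or its sub-stems) survives enumeration.
    """
    if stem_len < 1:
        raise ValueError("stem_len must be >= 1")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (backbone turn)")
    rng = random.Random(seed)
    n = 2 * stem_len + loop_len
    pairs = frozenset((t, n - 1 - t) for t in range(stem_len))
    planted = [Stem(i=0, j=n - 1, k=stem_len)]
    check = stem_len >= 3
    for _ in range(_MAX_ATTEMPTS):
        arm = "".join(rng.choice("GC") for _ in range(stem_len))
        seq = arm + "A" * loop_len + reverse_complement(arm)
        if not check or _only_substems(seq, planted, min_stem=3, min_loop=3):
            return seq, Structure(n=n, pairs=pairs)
    raise RuntimeError(
        f"could not generate a clean hairpin (stem_len={stem_len}, "
        f"loop_len={loop_len}) in {_MAX_ATTEMPTS} attempts"
    )


def planted_pseudoknot(
    stem_len_a: int, stem_len_b: int, seed: int | None = None
) -> tuple[str, Structure]:
    """An H-type pseudoknot with two planted crossing stems.

    Layout (spacers of length 3):

        armA . sp1 . armB . sp2 . revcomp(armA) . sp3 . revcomp(armB)

    Stem a pairs armA with its complement, stem b pairs armB with its
    complement, and their outer coordinates interleave
    (i_a < i_b < j_a < j_b). Arm a is drawn from G/C, arm b from A/U, and
    spacers from {A, C}; draws are rejected until the enumerated
    candidate set contains only the planted stems and their sub-stems.
    """
    if stem_len_a < 3 or stem_len_b < 3:
        raise ValueError("planted pseudoknot stems must have length >= 3")
    rng = random.Random(seed)
    sp = 3
    la, lb = stem_len_a, stem_len_b
    n = 2 * la + 2 * lb + 3 * sp
    i_b = la + sp
    j_a = la + sp + lb + sp + la - 1
    stem_a = Stem(i=0, j=j_a, k=la)
    stem_b = Stem(i=i_b, j=n - 1, k=lb)
    pairs = frozenset(stem_a.pairs()) | frozenset(stem_b.pairs())
    for _ in range(_MAX_ATTEMPTS):
        arm_a = "".join(rng.choice("GC") for _ in range(la))
        arm_b = "".join(rng.choice("AU") for _ in range(lb))
        spacers = ["".join(rng.choice("AC") for _ in range(sp)) for _ in range(3)]
        seq = (
            arm_a
            + spacers[0]
            + arm_b
            + spacers[1]
            + reverse_complement(arm_a)
            + spacers[2]
            + reverse_complement(arm_b)
        )
        if _only_substems(seq, [stem_a, stem_b], min_stem=3, min_loop=3):
            return seq, Structure(n=n, pairs=pairs)
    raise RuntimeError(
        f"could not generate a clean pseudoknot (lengths {la}, {lb}) "
        f"in {_MAX_ATTEMPTS} attempts"
    )
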
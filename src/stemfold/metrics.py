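"""Structure comparison: base-pair sensitivity and specificity.

Predictions are scored against a reference (e.g. experimentally
determined) structure by exact base-pair matching:

    sensitivity  sigma_SN = C / (C + M)   fraction of reference pairs found
    specificity  sigma_SP = C / (C + I)   fraction of predicted pairs correct

where C counts pairs present in both sets, M reference pairs missing from
the prediction, and I predicted pairs absent from the reference. No slip
tolerance is applied: a pair matches only at identical indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["Structure", "ComparisonResult", "compare_structures", "batch_report"]


@dataclass(frozen=True)
class Structure:
    """A secondary structure: a set of base pairs on a sequence of length n.

    Pairs are 0-based (p, q) with p < q; each base index appears in at
    most one pair.
    """

    n: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        seen: set[int] = set()
        for p, q in self.pairs:
            if not (0 <= p < q <= self.n - 1):
                raise ValueError(f"pair ({p}, {q}) out of range for n={self.n}")
            if p in seen or q in seen:
                raise ValueError(f"base index reused by pair ({p}, {q})")
            seen.add(p)
            seen.add(q)

    @property
    def paired_bases(self) -> frozenset[int]:
        return frozenset(b for pair in self.pairs for b in pair)


@dataclass(frozen=True)
class ComparisonResult:
    """Counts and scores from comparing predicted vs reference pairs."""

    C: int  # correctly identified pairs
    M: int  # reference pairs absent from the prediction
    I: int  # predicted pairs absent from the reference
    sensitivity: float
    specificity: float


def _ratio(num: int, den: int, both_empty: bool) -> float:
    # Degenerate denominators: when neither set has any pair the prediction
    # is exactly right (1.0); a zero denominator with the other side
    # non-empty means nothing was recovered/predicted correctly (0.0).
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def compare_structures(predicted: Structure, reference: Structure) -> ComparisonResult:
    """Compare two structures on the same sequence.

    Raises
    ------
    ValueError
        If the structures are defined on different sequence lengths.
    """
    if predicted.n != reference.n:
        raise ValueError(
            f"sequence length mismatch: predicted n={predicted.n}, "
            f"reference n={reference.n}"
        )
    c = len(predicted.pairs & reference.pairs)
    m = len(reference.pairs - predicted.pairs)
    i = len(predicted.pairs - reference.pairs)
    both_empty = not predicted.pairs and not reference.pairs
    return ComparisonResult(
        C=c,
        M=m,
        I=i,
        sensitivity=_ratio(c, c + m, both_empty),
        specificity=_ratio(c, c + i, both_empty),
    )


def batch_report(
    rows: Iterable[tuple[str, Structure, Structure]],
) -> str:
    """Tab-separated comparison report, one row per (name, predicted, reference).

    Columns: name, C, M, I, sensitivity, specificity; a final ``mean`` row
    averages the two scores over all records.
    """
    lines = ["name\tC\tM\tI\tsensitivity\tspecificity"]
    sns: list[float] = []
    sps: list[float] = []
    for name, predicted, reference in rows:
        res = compare_structures(predicted, reference)
        sns.append(res.sensitivity)
        sps.append(res.specificity)
        lines.append(
            f"{name}\t{res.C}\t{res.M}\t{res.I}"
            f"\t{res.sensitivity:.4f}\t{res.specificity:.4f}"
        )
    if sns:
        lines.append(
            f"mean\t\t\t\t{sum(sns) / len(sns):.4f}\t{sum(sps) / len(sps):.4f}"
        )
    return "\n".join(lines) + "\n"
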
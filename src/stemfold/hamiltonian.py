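"""Binary quadratic model of stem selection.

Each candidate stem is mapped to one binary variable q_i (the "qubit");
q_i = 1 selects the stem into the predicted structure. The Hamiltonian

    H = sum_i [ c_L (k_i - mu)^2 - c_B k_i^2 ] q_i
        - 2 c_B sum_{a<b} k_a k_b delta_ab q_a q_b
        + P sum_{a<b, overlap} q_a q_b

rewards configurations that maximize the squared total number of base
pairs, (sum_i k_i)^2, while penalizing short stems relative to mu, the
longest candidate's length. delta_ab = c_P when stems a and b cross
(pseudoknot) and 1 otherwise, so 0 <= c_P <= 1 scales down -- but does
not forbid -- crossing contributions. P is a finite constant standing in
for the infinite penalty that forbids two stems sharing a base.

Because the squared-sum expansion (sum k_i q_i)^2 = sum k_i^2 q_i +
2 sum_{a<b} k_a k_b q_a q_b relies on q_i^2 = q_i, the off-diagonal term
carries an explicit factor 2; with c_P = 1 and c_L = 0 the energy of any
valid selection is exactly -c_B (sum of selected k_i)^2.

Energies are reported as H (lower is better); the score used in reports
is -H (higher is better).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .metrics import Structure
from .stems import Stem, StemSet, is_overlap, is_pseudoknot

__all__ = [
    "HamiltonianParams",
    "BQMCoefficients",
    "Configuration",
    "EmptyStemSetError",
    "linear_coefficient",
    "quadratic_coefficient",
    "build_bqm",
    "evaluate_energy",
    "objective_direct",
    "decode_structure",
]

#: A configuration is a 0/1 selection vector over the StemSet order.
Configuration = Sequence[int]


class EmptyStemSetError(ValueError):
    """Raised when a BQM is requested for a sequence with no candidate stems.

    Callers should emit the fully unpaired structure in this case.
    """


def default_overlap_penalty(stems: StemSet, c_B: float, c_L: float, mu: int) -> float:
    """A finite stand-in for the infinite overlap penalty.

    Any configuration's attractive part is bounded below by
    -c_B (sum of all k_i)^2 and its length part above by c_L * N * mu^2,
    so this bound guarantees every overlap-containing configuration costs
    more than any overlap-free one while keeping coefficients finite for
    any sampler.
    """
    total_k = sum(s.k for s in stems)
    return c_B * total_k**2 + c_L * len(stems) * mu**2 + 1.0


@dataclass(frozen=True)
class HamiltonianParams:
    """Weights of the stem-selection Hamiltonian.

    Parameters
    ----------
    c_B : float
        Base-pair reward weight (> 0). Default 1.0.
    c_L : float
        Short-stem penalty weight (>= 0). Default 10.0.
    c_P : float
        Pseudoknot scale factor in [0, 1]; 1 leaves crossing stems
        unpenalized, values below 1 damp their pairwise reward. Default
        0.5. Values outside [0, 1] require ``allow_c_p_out_of_range``
        (negative values actively disfavor pseudoknots).
    mu : int
        Length of the longest stem in the candidate set; recomputed from
        the StemSet by :meth:`for_stems`, never taken on faith.
    overlap_penalty : float
        Finite positive constant replacing the infinite penalty on
        base-sharing stem pairs.
    """

    c_B: float = 1.0
    c_L: float = 10.0
    c_P: float = 0.5
    mu: int = 1
    overlap_penalty: float = field(default=10_000.0)
    allow_c_p_out_of_range: bool = False

    def __post_init__(self) -> None:
        if self.c_B <= 0:
            raise ValueError(f"c_B must be > 0, got {self.c_B}")
        if self.c_L < 0:
            raise ValueError(f"c_L must be >= 0, got {self.c_L}")
        if not self.allow_c_p_out_of_range and not (0.0 <= self.c_P <= 1.0):
            raise ValueError(
                f"c_P must lie in [0, 1], got {self.c_P}; pass "
                "allow_c_p_out_of_range=True to experiment outside that range"
            )
        if self.mu < 1:
            raise ValueError(f"mu must be >= 1, got {self.mu}")
        if self.overlap_penalty <= 0:
            raise ValueError("overlap_penalty must be positive")

    @classmethod
    def for_stems(
        cls,
        stems: StemSet,
        c_B: float = 1.0,
        c_L: float = 10.0,
        c_P: float = 0.5,
        allow_c_p_out_of_range: bool = False,
    ) -> "HamiltonianParams":
        """Build params for a candidate set, recomputing mu and the penalty."""
        if len(stems) == 0:
            raise EmptyStemSetError("no candidate stems in the set")
        mu = max(s.k for s in stems)
        penalty = default_overlap_penalty(stems, c_B=c_B, c_L=c_L, mu=mu)
        return cls(
            c_B=c_B,
            c_L=c_L,
            c_P=c_P,
            mu=mu,
            overlap_penalty=penalty,
            allow_c_p_out_of_range=allow_c_p_out_of_range,
        )


@dataclass(frozen=True)
class BQMCoefficients:
    """Linear terms h_i, quadratic terms J_ab (a < b), constant offset."""

    linear: dict[int, float]
    quadratic: dict[tuple[int, int], float]
    offset: float = 0.0

    def __post_init__(self) -> None:
        for a, b in self.quadratic:
            if a >= b:
                raise ValueError(f"quadratic key ({a}, {b}) must have a < b")
            if a not in self.linear or b not in self.linear:
                raise ValueError(f"quadratic key ({a}, {b}) lacks a linear entry")

    @property
    def num_variables(self) -> int:
        return len(self.linear)

    def to_json(self) -> str:
        """Plain-text coefficient table consumable by any QUBO sampler."""
        return json.dumps(
            {
                "linear": {str(i): h for i, h in sorted(self.linear.items())},
                "quadratic": [
                    [a, b, j] for (a, b), j in sorted(self.quadratic.items())
                ],
                "offset": self.offset,
            },
            indent=2,
        )


def linear_coefficient(stem: Stem, params: HamiltonianParams) -> float:
    """One-body coefficient: c_L (k - mu)^2 - c_B k^2."""
    if params.mu < stem.k:
        raise ValueError(f"mu={params.mu} smaller than stem length {stem.k}")
    return params.c_L * (stem.k - params.mu) ** 2 - params.c_B * stem.k**2


def quadratic_coefficient(a: Stem, b: Stem, params: HamiltonianParams) -> float:
    """Two-body coefficient for a pair of distinct stems.

    Overlapping stems get +overlap_penalty; compatible stems get the
    attractive cross term -2 c_B k_a k_b, scaled by c_P when they cross
    as a pseudoknot.
    """
    if a == b:
        raise ValueError("quadratic coefficient requires two distinct stems")
    if is_overlap(a, b):
        return params.overlap_penalty
    delta = params.c_P if is_pseudoknot(a, b) else 1.0
    return -2.0 * params.c_B * a.k * b.k * delta


def build_bqm(stems: StemSet, params: HamiltonianParams) -> BQMCoefficients:
    """Assemble the BQM coefficient maps over the StemSet order."""
    if len(stems) == 0:
        raise EmptyStemSetError("no candidate stems: emit the unpaired structure")
    linear = {idx: float(linear_coefficient(s, params)) for idx, s in enumerate(stems)}
    quadratic: dict[tuple[int, int], float] = {}
    for a in range(len(stems)):
        for b in range(a + 1, len(stems)):
            j = quadratic_coefficient(stems[a], stems[b], params)
            if j != 0.0:
                quadratic[(a, b)] = float(j)
    return BQMCoefficients(linear=linear, quadratic=quadratic, offset=0.0)


def evaluate_energy(bqm: BQMCoefficients, config: Configuration) -> float:
    """Energy H = sum_i h_i q_i + sum_{a<b} J_ab q_a q_b + offset."""
    bits = list(config)
    if len(bits) != bqm.num_variables:
        raise ValueError(
            f"configuration length {len(bits)} does not match "
            f"{bqm.num_variables} variables"
        )
    if any(b not in (0, 1) for b in bits):
        raise ValueError("configuration entries must be 0 or 1")
    energy = bqm.offset
    for i, h in bqm.linear.items():
        if bits[i]:
            energy += h
    for (a, b), j in bqm.quadratic.items():
        if bits[a] and bits[b]:
            energy += j
    return energy


def objective_direct(selected: list[Stem], params: HamiltonianParams) -> float:
    """Direct evaluation of the objective on a list of selected stems.

    Computed from the defining sums rather than the BQM coefficients --
    c_L sum (k_i - mu)^2 - c_B [sum k_i^2 + 2 sum_{a<b} k_a k_b delta_ab]
    with +overlap_penalty per overlapping pair -- so it serves as an
    independent cross-check of the coefficient assembly.
    """
    energy = 0.0
    for s in selected:
        energy += params.c_L * (s.k - params.mu) ** 2 - params.c_B * s.k**2
    for idx_a in range(len(selected)):
        for idx_b in range(idx_a + 1, len(selected)):
            a, b = selected[idx_a], selected[idx_b]
            if is_overlap(a, b):
                energy += params.overlap_penalty
            else:
                delta = params.c_P if is_pseudoknot(a, b) else 1.0
                energy += -2.0 * params.c_B * a.k * b.k * delta
    return energy


def decode_structure(config: Configuration, stems: StemSet) -> Structure:
    """Read the secondary structure off a binary configuration.

    Variables equal to 1 select their stems; the structure is the union of
    the selected stems' base pairs.

    Raises
    ------
    ValueError
        If two selected stems overlap (a base would pair twice).
    """
    bits = list(config)
    if len(bits) != len(stems):
        raise ValueError(
            f"configuration length {len(bits)} does not match {len(stems)} stems"
        )
    selected = [stems[i] for i, b in enumerate(bits) if b]
    for idx_a in range(len(selected)):
        for idx_b in range(idx_a + 1, len(selected)):
            if is_overlap(selected[idx_a], selected[idx_b]):
                raise ValueError(
                    f"invalid configuration: stems {selected[idx_a]} and "
                    f"{selected[idx_b]} overlap"
                )
    pairs = frozenset(pair for s in selected for pair in s.pairs())
    return Structure(n=len(stems.sequence), pairs=pairs)
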
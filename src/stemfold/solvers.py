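"""Minimization of the stem-selection BQM.

Three solvers share the same objective:

* :func:`solve_exact` -- global minimum over all 2^N configurations, by
  plain full scan or by depth-first search that prunes branches forced to
  contain an overlapping stem pair (the penalty construction guarantees
  such branches cannot hold the minimum, so both routes agree).
* :func:`solve_sa` -- single Metropolis chain under geometric cooling.
* :func:`solve_remc` -- replica exchange (parallel tempering): several
  Metropolis chains at fixed inverse temperatures beta that periodically
  attempt to swap states between neighbors with probability
  min(1, exp((beta_a - beta_b) (E_a - E_b))).

The Monte Carlo move set follows the add / remove / swap scheme, each
drawn with equal probability; moves that cannot apply (removing from an
empty state, swapping in an already-selected stem) count as rejected
steps. All stochastic paths are driven by explicit integer seeds and are
fully reproducible.

:func:`sampler_adapter` wraps any external QUBO sampler (e.g. a quantum
annealer client) that accepts linear/quadratic coefficient maps and
returns bit vectors with energies; reported energies are verified by
recomputation before being trusted.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .hamiltonian import BQMCoefficients, evaluate_energy
from .stems import StemSet

__all__ = [
    "SolveResult",
    "REMCParams",
    "SASchedule",
    "SamplerInconsistentError",
    "search_space_size",
    "solve_exact",
    "solve_sa",
    "solve_remc",
    "sampler_adapter",
]

_MAX_EXP_ARG = 700.0  # beyond this exp() overflows a double


def search_space_size(n_stems: int) -> int:
    """Number of binary configurations over ``n_stems`` variables: 2^N."""
    if n_stems < 0:
        raise ValueError("number of stems must be non-negative")
    return 2**n_stems


@dataclass(frozen=True)
class SolveResult:
    """Outcome of a solve: the lowest-energy configuration seen."""

    best_config: tuple[int, ...]
    best_energy: float
    solver_name: str
    seed: int | None = None
    steps_executed: int = 0
    samples: tuple[tuple[tuple[int, ...], float], ...] | None = None
    stats: dict = field(default_factory=dict)

    @property
    def score(self) -> float:
        """The negated energy -H; larger is better."""
        return -self.best_energy

    def to_json_dict(self, stems: StemSet | None = None) -> dict:
        out = {
            "solver": self.solver_name,
            "seed": self.seed,
            "steps_executed": self.steps_executed,
            "config": list(self.best_config),
            "energy": self.best_energy,
            "score": self.score,
        }
        if stems is not None:
            out["stems"] = [
                {"index": i, "i": s.i, "j": s.j, "k": s.k}
                for i, s in enumerate(stems)
                if self.best_config[i]
            ]
        return out

    def to_json(self, stems: StemSet | None = None) -> str:
        return json.dumps(self.to_json_dict(stems), indent=2)


class SamplerInconsistentError(RuntimeError):
    """An external sampler reported energies that do not match the BQM."""


# ---------------------------------------------------------------------------
# dense views of the BQM, shared by all solvers


def _dense(bqm: BQMCoefficients) -> tuple[list[float], list[list[float]]]:
    n = bqm.num_variables
    h = [0.0] * n
    for i, v in bqm.linear.items():
        h[i] = v
    j = [[0.0] * n for _ in range(n)]
    for (a, b), v in bqm.quadratic.items():
        j[a][b] = v
        j[b][a] = v
    return h, j


# ---------------------------------------------------------------------------
# exact enumeration


def solve_exact(
    bqm: BQMCoefficients,
    stems: StemSet | None = None,
    max_qubits: int = 25,
    method: str = "prune",
) -> SolveResult:
    """Global minimum over all 2^N configurations.

    Ties are broken toward the lexicographically smallest bit vector
    (variable 0 most significant, 0 before 1). ``method="scan"`` evaluates
    every configuration; ``method="prune"`` (default) skips branches that
    already contain an overlapping stem pair, which cannot hold the
    minimum because the overlap penalty exceeds any attainable reward.
    Both methods return identical minima.

    Raises
    ------
    ValueError
        If N exceeds ``max_qubits``; use :func:`solve_sa` or
        :func:`solve_remc` for larger instances.
    """
    n = bqm.num_variables
    if n == 0:
        return SolveResult(
            best_config=(), best_energy=bqm.offset, solver_name=f"exact-{method}"
        )
    if n > max_qubits:
        raise ValueError(
            f"exact enumeration over 2^{n} configurations exceeds the cap of "
            f"{max_qubits} variables; use a stochastic solver (sa, remc) instead"
        )
    if method not in ("prune", "scan"):
        raise ValueError(f"unknown exact method {method!r}")

    h, j = _dense(bqm)
    penalty_edges: list[set[int]] | None = None
    if method == "prune":
        # an edge is a forbidden (overlap-penalized) pair iff its coefficient
        # is the positive penalty; all attractive couplings are <= 0
        penalty_edges = [set() for _ in range(n)]
        for (a, b), v in bqm.quadratic.items():
            if v > 0:
                penalty_edges[a].add(b)
                penalty_edges[b].add(a)

    best_energy = math.inf
    best_bits: tuple[int, ...] = ()
    bits = [0] * n
    leaves = 0

    # iterative DFS in lexicographic order: at depth d branch on bits[d],
    # exploring 0 before 1, so the first leaf attaining the minimum is the
    # lexicographically smallest; strict '<' preserves that tie-break.
    def rec(depth: int, energy: float) -> None:
        nonlocal best_energy, best_bits, leaves
        if depth == n:
            leaves += 1
            if energy < best_energy:
                best_energy = energy
                best_bits = tuple(bits)
            return
        bits[depth] = 0
        rec(depth + 1, energy)
        if penalty_edges is not None and any(
            bits[other] for other in penalty_edges[depth] if other < depth
        ):
            bits[depth] = 0
            return
        delta = h[depth]
        row = j[depth]
        for other in range(depth):
            if bits[other]:
                delta += row[other]
        bits[depth] = 1
        rec(depth + 1, energy + delta)
        bits[depth] = 0

    old_limit = None
    import sys

    if n + 16 > sys.getrecursionlimit():
        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(n + 64)
    try:
        rec(0, bqm.offset)
    finally:
        if old_limit is not None:
            sys.setrecursionlimit(old_limit)

    return SolveResult(
        best_config=best_bits,
        best_energy=best_energy,
        solver_name=f"exact-{method}",
        steps_executed=leaves,
    )


# ---------------------------------------------------------------------------
# Monte Carlo machinery


class _Chain:
    """One Metropolis chain over stem-selection states.

    State is a set of selected variable indices; energy is maintained
    incrementally (h_s + sum of couplings to the current selection per
    flip)."""

    __slots__ = ("h", "j", "n", "rng", "state", "energy", "best_energy", "best_state")

    def __init__(
        self,
        h: list[float],
        j: list[list[float]],
        rng: random.Random,
        init_max_stems: int,
    ):
        self.h = h
        self.j = j
        self.n = len(h)
        self.rng = rng
        n_init = rng.randint(0, min(init_max_stems, self.n))
        self.state: set[int] = set(rng.sample(range(self.n), n_init))
        self.energy = self._full_energy()
        self.best_energy = self.energy
        self.best_state = frozenset(self.state)

    def _full_energy(self) -> float:
        e = 0.0
        sel = sorted(self.state)
        for idx, a in enumerate(sel):
            e += self.h[a]
            row = self.j[a]
            for b in sel[idx + 1 :]:
                e += row[b]
        return e

    def _delta_add(self, t: int) -> float:
        row = self.j[t]
        return self.h[t] + sum(row[u] for u in self.state)

    def _delta_remove(self, s: int) -> float:
        row = self.j[s]
        return -self.h[s] - sum(row[u] for u in self.state if u != s)

    def _draw_absent(self) -> int | None:
        """Uniform draw from variables outside the current state."""
        if len(self.state) >= self.n:
            return None
        while True:
            t = self.rng.randrange(self.n)
            if t not in self.state:
                return t

    def _metropolis(self, delta: float, beta: float) -> bool:
        if delta <= 0:
            return True
        arg = beta * delta
        if arg > _MAX_EXP_ARG:
            return False
        return self.rng.random() < math.exp(-arg)

    def step(self, beta: float) -> bool:
        """One add/remove/swap move; returns True if accepted."""
        move = self.rng.randrange(3)
        if move == 0:  # add
            t = self._draw_absent()
            if t is None:
                return False
            delta = self._delta_add(t)
            if self._metropolis(delta, beta):
                self.state.add(t)
                self.energy += delta
                self._note_best()
                return True
            return False
        if move == 1:  # remove
            if not self.state:
                return False
            s = self.rng.choice(tuple(self.state))
            delta = self._delta_remove(s)
            if self._metropolis(delta, beta):
                self.state.discard(s)
                self.energy += delta
                self._note_best()
                return True
            return False
        # swap: replace a selected stem by one drawn from all others
        if not self.state:
            return False
        s = self.rng.choice(tuple(self.state))
        if self.n < 2:
            return False
        t = self.rng.randrange(self.n - 1)
        if t >= s:
            t += 1
        if t in self.state:
            return False
        row_t, row_s = self.j[t], self.j[s]
        delta = self.h[t] - self.h[s] + sum(
            row_t[u] - row_s[u] for u in self.state if u != s
        )
        if self._metropolis(delta, beta):
            self.state.discard(s)
            self.state.add(t)
            self.energy += delta
            self._note_best()
            return True
        return False

    def _note_best(self) -> None:
        if self.energy < self.best_energy:
            self.best_energy = self.energy
            self.best_state = frozenset(self.state)


def _state_to_bits(state: frozenset[int] | set[int], n: int) -> tuple[int, ...]:
    return tuple(1 if i in state else 0 for i in range(n))


@dataclass(frozen=True)
class SASchedule:
    """Geometric (exponential) cooling schedule for simulated annealing.

    The start temperature defaults to 10, comparable to the cost
    c_B * k^2 of dropping a short stem at default weights, so the early
    phase genuinely randomizes; the final temperature mirrors the coldest
    replica (beta = 30) of the replica-exchange ladder.
    """

    t_start: float = 10.0
    t_end: float = 1.0 / 30.0
    n_steps: int = 20_000

    def __post_init__(self) -> None:
        if self.t_start <= 0 or self.t_end <= 0:
            raise ValueError("temperatures must be positive")
        if self.t_end > self.t_start:
            raise ValueError("schedule must cool: t_end <= t_start")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def temperature(self, step: int) -> float:
        if self.n_steps == 1:
            return self.t_start
        frac = step / (self.n_steps - 1)
        return self.t_start * (self.t_end / self.t_start) ** frac


def solve_sa(
    bqm: BQMCoefficients,
    stems: StemSet | None = None,
    schedule: SASchedule | None = None,
    seed: int | None = None,
    init_max_stems: int = 5,
) -> SolveResult:
    """Single-chain simulated annealing with geometric cooling.

    Uses the same add/remove/swap move set as the replica-exchange
    solver; returns the best state seen over the whole trajectory.
    """
    schedule = schedule or SASchedule()
    n = bqm.num_variables
    if n == 0:
        return SolveResult(best_config=(), best_energy=bqm.offset,
                           solver_name="sa", seed=seed)
    rng = random.Random(seed)
    h, j = _dense(bqm)
    chain = _Chain(h, j, rng, init_max_stems)
    accepted = 0
    for step in range(schedule.n_steps):
        beta = 1.0 / schedule.temperature(step)
        if chain.step(beta):
            accepted += 1
    return SolveResult(
        best_config=_state_to_bits(chain.best_state, n),
        best_energy=chain.best_energy + bqm.offset,
        solver_name="sa",
        seed=seed,
        steps_executed=schedule.n_steps,
        stats={"move_acceptance": accepted / schedule.n_steps},
    )


@dataclass(frozen=True)
class REMCParams:
    """Replica-exchange parameters.

    Defaults follow the reference regime: 64 replicas with inverse
    temperatures beta spaced geometrically from 1 to 30, 10^6 Monte Carlo
    steps per replica, exchange attempts every 10^3 steps, and initial
    states of up to 5 randomly selected stems. For test-scale instances
    these are typically scaled down.
    """

    n_replicas: int = 64
    beta_min: float = 1.0
    beta_max: float = 30.0
    total_steps: int = 10**6
    exchange_stride: int = 10**3
    init_max_stems: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise ValueError("need at least 2 replicas")
        if not (0 < self.beta_min < self.beta_max):
            raise ValueError("require 0 < beta_min < beta_max")
        if self.exchange_stride < 1 or self.exchange_stride >= self.total_steps:
            raise ValueError("require 1 <= exchange_stride < total_steps")

    def betas(self) -> list[float]:
        """Geometric beta ladder from beta_min to beta_max (increasing)."""
        r = self.n_replicas
        ratio = self.beta_max / self.beta_min
        return [self.beta_min * ratio ** (idx / (r - 1)) for idx in range(r)]


def solve_remc(
    bqm: BQMCoefficients,
    stems: StemSet | None = None,
    params: REMCParams | None = None,
) -> SolveResult:
    """Replica-exchange Monte Carlo minimization.

    Each replica runs an independent Metropolis chain at its fixed beta
    between exchange points; at each exchange point neighboring replicas
    attempt to swap *states* with probability
    min(1, exp((beta_a - beta_b)(E_a - E_b))), alternating even and odd
    neighbor pairs. The result is the minimum-energy state seen by any
    replica at any step.
    """
    params = params or REMCParams()
    n = bqm.num_variables
    if n == 0:
        return SolveResult(best_config=(), best_energy=bqm.offset,
                           solver_name="remc", seed=params.seed)
    master = random.Random(params.seed)
    chain_seeds = [master.randrange(2**31) for _ in range(params.n_replicas)]
    exchange_rng = random.Random(master.randrange(2**31))

    h, j = _dense(bqm)
    betas = params.betas()
    chains = [
        _Chain(h, j, random.Random(s), params.init_max_stems) for s in chain_seeds
    ]

    steps_done = 0
    attempts = 0
    exchanges = 0
    block = 0
    while steps_done < params.total_steps:
        stride = min(params.exchange_stride, params.total_steps - steps_done)
        for chain, beta in zip(chains, betas):
            for _ in range(stride):
                chain.step(beta)
        steps_done += stride
        if steps_done >= params.total_steps:
            break
        start = block % 2  # alternate even / odd neighbor pairs
        for a in range(start, params.n_replicas - 1, 2):
            b = a + 1
            attempts += 1
            arg = (betas[a] - betas[b]) * (chains[a].energy - chains[b].energy)
            accept = arg >= 0 or exchange_rng.random() < math.exp(max(arg, -_MAX_EXP_ARG))
            if accept:
                exchanges += 1
                chains[a].state, chains[b].state = chains[b].state, chains[a].state
                chains[a].energy, chains[b].energy = chains[b].energy, chains[a].energy
                chains[a]._note_best()
                chains[b]._note_best()
        block += 1

    best_chain = min(chains, key=lambda c: c.best_energy)
    return SolveResult(
        best_config=_state_to_bits(best_chain.best_state, n),
        best_energy=best_chain.best_energy + bqm.offset,
        solver_name="remc",
        seed=params.seed,
        steps_executed=params.total_steps * params.n_replicas,
        stats={
            "exchange_attempts": attempts,
            "exchange_accepted": exchanges,
            "exchange_acceptance": exchanges / attempts if attempts else float("nan"),
            "n_replicas": params.n_replicas,
        },
    )


# ---------------------------------------------------------------------------
# external sampler adapter


ExternalSampler = Callable[
    [dict[int, float], dict[tuple[int, int], float], float],
    Iterable[tuple[Sequence[int], float]],
]


def sampler_adapter(
    bqm: BQMCoefficients,
    external_sampler: ExternalSampler,
    name: str = "external",
    energy_tolerance: float = 1e-6,
) -> SolveResult:
    """Run an external QUBO sampler and validate its reported energies.

    The sampler is called with (linear, quadratic, offset) and must yield
    (bit-vector, energy) samples. Every reported energy is recomputed from
    the BQM; a discrepancy beyond ``energy_tolerance`` (absolute, scaled
    by magnitude) flags the sampler as inconsistent.
    """
    raw = list(external_sampler(dict(bqm.linear), dict(bqm.quadratic), bqm.offset))
    if not raw:
        raise SamplerInconsistentError(f"sampler {name!r} returned no samples")
    samples: list[tuple[tuple[int, ...], float]] = []
    for bits, reported in raw:
        bits = tuple(int(b) for b in bits)
        actual = evaluate_energy(bqm, bits)
        tol = energy_tolerance * max(1.0, abs(actual))
        if abs(actual - reported) > tol:
            raise SamplerInconsistentError(
                f"sampler {name!r} reported energy {reported} for a "
                f"configuration whose energy is {actual}"
            )
        samples.append((bits, actual))
    best_bits, best_energy = min(samples, key=lambda s: (s[1], s[0]))
    return SolveResult(
        best_config=best_bits,
        best_energy=best_energy,
        solver_name=f"adapter:{name}",
        samples=tuple(samples),
    )
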
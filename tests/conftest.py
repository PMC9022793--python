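"""Shared fixtures and independent oracles.

The brute-force stem enumerator and the full-scan BQM minimizer here are
deliberately naive re-implementations used only to cross-check the
package's faster routines.
"""

from __future__ import annotations

import itertools

import pytest

from stemfold.hamiltonian import BQMCoefficients, evaluate_energy
from stemfold.stems import ALLOWED_PAIRS


def brute_force_stems(seq: str, min_stem: int, min_loop: int) -> set[tuple[int, int, int]]:
    """All (i, j, k) by direct triple loop over candidates.

    Checks every implied pair against the allowed-pair table and the
    enclosed-loop constraint; no shortcut shared with the implementation.
    """
    n = len(seq)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(min_stem, n):
                if j - i + 1 - 2 * k < min_loop:
                    break
                ok = all(
                    seq[i + t] + seq[j - t] in ALLOWED_PAIRS for t in range(k)
                )
                if ok:
                    out.add((i, j, k))
    return out


def full_scan_minimum(bqm: BQMCoefficients) -> tuple[tuple[int, ...], float]:
    """Minimum over all 2^N configurations by exhaustive evaluation.

    Iterates in lexicographic bit-vector order and keeps the first
    strict minimum, matching the documented tie-break.
    """
    n = bqm.num_variables
    best_bits: tuple[int, ...] = ()
    best_energy = float("inf")
    for bits in itertools.product((0, 1), repeat=n):
        e = evaluate_energy(bqm, bits)
        if e < best_energy:
            best_energy = e
            best_bits = bits
    return best_bits, best_energy


@pytest.fixture
def fig_sequence() -> str:
    """An 18-mer whose candidate set includes a crossing (pseudoknot) pair."""
    return "GGAAGCAAACAUCCCUGU"
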
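"""Reading and writing sequences and secondary structures.

Supported formats:

* FASTA (via Biopython) for sequences;
* classic 6-column connectivity table (CT), 1-based, reciprocity
  enforced on read;
* dot-bracket with up to four bracket layers ``()``, ``[]``, ``{}``,
  ``<>`` so that pseudoknotted (crossing) pairs can be encoded; layers
  are assigned by greedy coloring of the pair-crossing graph, in that
  fixed order, which makes output deterministic;
* a JSON result bundle tying together sequence, stems, configuration,
  energy and metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

from Bio import SeqIO

from .metrics import Structure
from .stems import clean_sequence

__all__ = [
    "StructureRecord",
    "read_fasta",
    "read_ct",
    "write_ct",
    "read_dotbracket",
    "write_dotbracket",
    "result_bundle",
]

_OPEN = "([{<"
_CLOSE = ")]}>"
_CLOSE_OF = dict(zip(_OPEN, _CLOSE))
_OPEN_OF = dict(zip(_CLOSE, _OPEN))


@dataclass(frozen=True)
class StructureRecord:
    """A named sequence together with its secondary structure."""

    name: str
    sequence: str
    structure: Structure

    def __post_init__(self) -> None:
        if len(self.sequence) != self.structure.n:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"structure length {self.structure.n}"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, normalized RNA sequence) tuples from a FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, clean_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


# ---------------------------------------------------------------------------
# CT (connectivity table)


def read_ct(source: str | Path | TextIO) -> StructureRecord:
    """Parse a classic 6-column CT file.

    Header: ``N name``; then one line per base with columns
    (index, base, index-1, index+1, pairing partner or 0, index), all
    1-based. Pairing must be reciprocal.
    """
    if hasattr(source, "read"):
        text = source.read()
        origin = "<stream>"
    else:
        origin = str(source)
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{origin}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{origin}:1: CT header must start with the base count") from exc
    name = header[1] if len(header) > 1 else "structure"
    if len(lines) - 1 != n:
        raise ValueError(
            f"{origin}: header declares {n} bases but {len(lines) - 1} "
            "data lines follow"
        )
    seq_chars: list[str] = []
    partner: list[int] = []  # 1-based partner per base, 0 = unpaired
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split()
        if len(cols) < 5:
            raise ValueError(f"{origin}:{lineno}: expected >= 5 columns")
        try:
            idx = int(cols[0])
            pair = int(cols[4])
        except ValueError as exc:
            raise ValueError(f"{origin}:{lineno}: non-integer index column") from exc
        if idx != lineno - 1:
            raise ValueError(
                f"{origin}:{lineno}: base index {idx} out of order "
                f"(expected {lineno - 1})"
            )
        if pair < 0 or pair > n:
            raise ValueError(f"{origin}:{lineno}: pairing index {pair} out of range")
        seq_chars.append(cols[1])
        partner.append(pair)
    for base_1 in range(1, n + 1):
        mate = partner[base_1 - 1]
        if mate == 0:
            continue
        if mate == base_1:
            raise ValueError(f"{origin}:{base_1 + 1}: base pairs with itself")
        if partner[mate - 1] != base_1:
            raise ValueError(
                f"{origin}:{base_1 + 1}: non-reciprocal pairing "
                f"{base_1} -> {mate} but {mate} -> {partner[mate - 1]}"
            )
    pairs = frozenset(
        (base_1 - 1, partner[base_1 - 1] - 1)
        for base_1 in range(1, n + 1)
        if partner[base_1 - 1] > base_1
    )
    sequence = clean_sequence("".join(seq_chars))
    return StructureRecord(name=name, sequence=sequence, structure=Structure(n=n, pairs=pairs))


def write_ct(record: StructureRecord, path: str | Path | None = None) -> str:
    """Render a record as classic 6-column CT text; optionally write it."""
    n = record.structure.n
    partner = [0] * n
    for p, q in record.structure.pairs:
        partner[p] = q + 1
        partner[q] = p + 1
    lines = [f"{n} {record.name}"]
    for idx0, base in enumerate(record.sequence):
        idx1 = idx0 + 1
        nxt = idx1 + 1 if idx1 < n else 0
        lines.append(f"{idx1} {base} {idx1 - 1} {nxt} {partner[idx0]} {idx1}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# dot-bracket


def _crossing(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (p1, q1), (p2, q2) = a, b
    return (p1 < p2 < q1 < q2) or (p2 < p1 < q2 < q1)


def write_dotbracket(record: StructureRecord) -> str:
    """Encode a structure in layered dot-bracket notation.

    Pairs are greedily assigned, in (p, q) order, to the first bracket
    layer in which they cross no previously placed pair. Structures whose
    crossing graph needs more than four colors cannot be encoded.
    """
    layers: list[list[tuple[int, int]]] = [[] for _ in _OPEN]
    for pair in sorted(record.structure.pairs):
        for layer in layers:
            if not any(_crossing(pair, placed) for placed in layer):
                layer.append(pair)
                break
        else:
            raise ValueError(
                "structure requires more than 4 bracket layers to encode"
            )
    chars = ["."] * record.structure.n
    for depth, layer in enumerate(layers):
        for p, q in layer:
            chars[p] = _OPEN[depth]
            chars[q] = _CLOSE[depth]
    return f">{record.name}\n{record.sequence}\n{''.join(chars)}\n"


def read_dotbracket(text: str) -> StructureRecord:
    """Parse one dot-bracket record: optional ``>name``, sequence, brackets."""
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty dot-bracket input")
    name = "structure"
    if lines[0].startswith(">"):
        name = lines[0][1:].strip() or name
        lines = lines[1:]
    if len(lines) < 2:
        raise ValueError("dot-bracket input needs a sequence line and a bracket line")
    sequence = clean_sequence(lines[0])
    brackets = lines[1]
    if len(brackets) != len(sequence):
        raise ValueError(
            f"bracket line length {len(brackets)} does not match sequence "
            f"length {len(sequence)}"
        )
    stacks: dict[str, list[int]] = {ch: [] for ch in _OPEN}
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(brackets):
        if ch == ".":
            continue
        if ch in _CLOSE_OF:
            stacks[ch].append(idx)
        elif ch in _OPEN_OF:
            stack = stacks[_OPEN_OF[ch]]
            if not stack:
                raise ValueError(f"unbalanced bracket {ch!r} at position {idx + 1}")
            pairs.add((stack.pop(), idx))
        else:
            raise ValueError(f"unknown structure symbol {ch!r} at position {idx + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(
                f"unbalanced bracket {opener!r} opened at position {stack[-1] + 1}"
            )
    return StructureRecord(
        name=name,
        sequence=sequence,
        structure=Structure(n=len(sequence), pairs=frozenset(pairs)),
    )


def read_dotbracket_file(path: str | Path) -> list[StructureRecord]:
    """Parse a multi-record dot-bracket file (records begin with ``>``)."""
    text = Path(path).read_text()
    chunks: list[list[str]] = []
    for line in text.splitlines():
        if line.startswith(">"):
            chunks.append([line])
        elif line.strip():
            if not chunks:
                chunks.append([])
            chunks[-1].append(line)
    records = [read_dotbracket("\n".join(chunk)) for chunk in chunks if chunk]
    if not records:
        raise ValueError(f"no dot-bracket records found in {path}")
    return records


# ---------------------------------------------------------------------------
# JSON result bundle


def result_bundle(
    record: StructureRecord,
    stems_table: list[dict] | None = None,
    config: list[int] | None = None,
    energy: float | None = None,
    metrics: dict | None = None,
    provenance: dict | None = None,
) -> str:
    """Serialize a prediction (and optional metrics) to a JSON document."""
    out: dict = {
        "name": record.name,
        "sequence": record.sequence,
        "pairs": sorted([p, q] for p, q in record.structure.pairs),
    }
    if stems_table is not None:
        out["stems"] = stems_table
    if config is not None:
        out["configuration"] = config
    if energy is not None:
        out["energy"] = energy
        out["score"] = -energy
    if metrics is not None:
        out["metrics"] = metrics
    if provenance is not None:
        out["provenance"] = provenance
    return json.dumps(out, indent=2, sort_keys=True)
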
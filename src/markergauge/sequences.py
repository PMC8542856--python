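"""Low-level nucleotide utilities: IUPAC codes, complements, FASTA I/O.

The FASTA reader is deliberately minimal: records are (id, description,
sequence) with sequences uppercased, and malformed input (sequence data
before any header) is reported with the offending line number.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Sequence, Tuple

# IUPAC nucleotide codes -> set of unambiguous bases they stand for.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"{message} (line {line})")
        self.line = line


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_nucleotide(seq: str) -> bool:
    return all(b in IUPAC for b in seq.upper())


def bases_compatible(a: str, b: str) -> bool:
    """True when two IUPAC codes can denote the same base (set intersection)."""
    try:
        return bool(IUPAC[a] & IUPAC[b])
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from None


def read_fasta(path: str | os.PathLike) -> List[Tuple[str, str, str]]:
    """Read a FASTA file into a list of (id, description, sequence).

    Sequences are uppercased and input order is preserved. An empty file
    yields an empty list.
    """
    records: List[Tuple[str, str, List[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                name, _, desc = header.partition(" ")
                if not name:
                    raise FastaParseError("empty FASTA header", lineno)
                records.append((name, desc, []))
            else:
                if not records:
                    raise FastaParseError("sequence data before first FASTA header", lineno)
                records[-1][2].append(line.upper())
    return [(name, desc, "".join(chunks)) for name, desc, chunks in records]


def write_fasta(path: str | os.PathLike,
                records: Iterable[Tuple[str, str] | Tuple[str, str, str]],
                width: int = 80) -> None:
    """Write records as FASTA, wrapping sequence lines at `width` columns.

    Records are (id, sequence) or (id, description, sequence).
    """
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 2:
                name, seq = rec
                desc = ""
            else:
                name, desc, seq = rec
            header = f">{name} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def gc_fraction(seq: str) -> float | None:
    """G+C fraction over unambiguous bases only; None if no A/C/G/T present."""
    seq = seq.upper()
    gc = sum(1 for b in seq if b in "GC")
    at = sum(1 for b in seq if b in "AT")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length gap-free sequences."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal-length sequences")
    if not a:
        raise ValueError("empty sequences")
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / len(a)


def random_sequence(rng, length: int) -> str:
    """Uniform random A/C/G/T sequence from a numpy Generator."""
    return "".join(rng.choice(["A", "C", "G", "T"], size=length))
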
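"""Sequence I/O and the structured read-identifier scheme.

EST reads carry their provenance in the identifier itself: source library
(whole embryo or adult CNS), sequencing center, and sequencing strategy
(5'->3' or 3'->5').  The scheme used here is pipe-delimited::

    LIB|CENTER|STRAND|CLONE      e.g.  EMB|JGI|F|clone0001

with ``LIB`` in {EMB, CNS} and ``STRAND`` in {F, R}.  It round-trips
losslessly through :func:`parse_identifier` / :func:`format_identifier`.

FASTA and QUAL use the NCBI dialect (QUAL shares FASTA headers; qualities
are whitespace-separated integers).  Readers are strict: a malformed header
or an illegal base raises :class:`FormatError` naming the offending line.
All coordinates written to TSV reports are 0-based half-open.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "IdentifierError",
    "SourceTag",
    "SeqRecord",
    "LIBRARIES",
    "STRATEGIES",
    "parse_identifier",
    "format_identifier",
    "contig_id",
    "read_fasta",
    "write_fasta",
    "read_qual",
    "write_qual",
]

DNA_ALPHABET = frozenset("ACGTN")

LIBRARIES = ("embryo", "adult_cns")
STRATEGIES = ("five_to_three", "three_to_five")

_LIB_CODE = {"embryo": "EMB", "adult_cns": "CNS"}
_LIB_FROM_CODE = {v: k for k, v in _LIB_CODE.items()}
_STRAT_CODE = {"five_to_three": "F", "three_to_five": "R"}
_STRAT_FROM_CODE = {v: k for k, v in _STRAT_CODE.items()}


class FormatError(ValueError):
    """Raised for malformed FASTA/QUAL input; message names the line number."""


class IdentifierError(ValueError):
    """Raised when a read identifier does not follow the LIB|CENTER|STRAND|CLONE scheme."""


@dataclass(frozen=True)
class SourceTag:
    """Provenance of one EST read: library, center, sequencing strategy, clone."""

    library: str
    center: str
    strategy: str
    clone_id: str

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise IdentifierError(f"unknown library {self.library!r}")
        if self.strategy not in STRATEGIES:
            raise IdentifierError(f"unknown strategy {self.strategy!r}")


def format_identifier(tag: SourceTag) -> str:
    """Render a :class:`SourceTag` as ``LIB|CENTER|STRAND|CLONE``."""
    return "|".join(
        (_LIB_CODE[tag.library], tag.center, _STRAT_CODE[tag.strategy], tag.clone_id)
    )


def parse_identifier(identifier: str) -> SourceTag:
    """Parse ``LIB|CENTER|STRAND|CLONE`` into a :class:`SourceTag`.

    Raises :class:`IdentifierError` on any deviation from the scheme.
    """
    parts = identifier.split("|")
    if len(parts) != 4:
        raise IdentifierError(f"identifier {identifier!r} does not have 4 '|'-fields")
    lib, center, strand, clone = parts
    if lib not in _LIB_FROM_CODE:
        raise IdentifierError(f"identifier {identifier!r}: unknown library code {lib!r}")
    if strand not in _STRAT_FROM_CODE:
        raise IdentifierError(f"identifier {identifier!r}: unknown strand code {strand!r}")
    if not center or not clone:
        raise IdentifierError(f"identifier {identifier!r}: empty center or clone field")
    return SourceTag(_LIB_FROM_CODE[lib], center, _STRAT_FROM_CODE[strand], clone)


@dataclass
class SeqRecord:
    """One read: identifier, DNA bases over {A,C,G,T,N}, optional phred qualities.

    Lowercase input bases are uppercased; ``U`` and any other non-DNA letter
    are rejected.  When qualities are present they must match the sequence
    length.
    """

    id: str
    bases: str
    quals: list[int] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bases = self.bases.upper()
        bad = set(bases) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)} (DNA over ACGTN only)"
            )
        self.bases = bases
        if self.quals is not None and len(self.quals) != len(bases):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} qualities for {len(bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def tag(self) -> SourceTag:
        return parse_identifier(self.id)


def contig_id(member_ids: Iterable[str]) -> str:
    """Deterministic contig identifier derived from the sorted member id list.

    ``ctg-`` plus the first 12 hex chars of a SHA-1 over the sorted,
    newline-joined member ids; order-independent by construction.
    """
    joined = "\n".join(sorted(member_ids))
    return "ctg-" + hashlib.sha1(joined.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# FASTA / QUAL

def _parse_header(line: str, lineno: int, path: str) -> tuple[str, str]:
    if not line.startswith(">") or len(line) == 1:
        raise FormatError(f"{path}:{lineno}: expected '>id [description]' header")
    head = line[1:].strip()
    if not head:
        raise FormatError(f"{path}:{lineno}: empty FASTA header")
    ident, _, desc = head.partition(" ")
    return ident, desc.strip()


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, in file order.

    The description after the first whitespace is kept separate from the id.
    An empty file yields an empty list.  Malformed headers or illegal
    characters raise :class:`FormatError` naming the line number.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    ident: str | None = None
    desc = ""
    chunks: list[str] = []
    start_line = 0

    def flush() -> None:
        if ident is None:
            return
        bases = "".join(chunks)
        try:
            records.append(SeqRecord(ident, bases, description=desc))
        except ValueError as exc:
            raise FormatError(f"{path}:{start_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                ident, desc = _parse_header(line, lineno, str(path))
                chunks = []
                start_line = lineno
            else:
                if ident is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first '>' header")
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def read_qual(path: str | Path, records: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Attach per-base qualities from a QUAL file to matching records.

    QUAL entries are keyed by the same ids as the FASTA.  Records without a
    QUAL entry keep ``quals=None``.  A quality list whose length differs
    from the record's sequence raises :class:`FormatError` naming the id.
    """
    path = Path(path)
    table: dict[str, list[int]] = {}
    ident = None
    values: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ident is not None:
                    table[ident] = values
                ident, _ = _parse_header(line, lineno, str(path))
                values = []
            else:
                if ident is None:
                    raise FormatError(f"{path}:{lineno}: qualities before first '>' header")
                try:
                    values.extend(int(tok) for tok in line.split())
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer quality value") from exc
        if ident is not None:
            table[ident] = values

    out: list[SeqRecord] = []
    for rec in records:
        if rec.id in table:
            quals = table[rec.id]
            if len(quals) != len(rec.bases):
                raise FormatError(
                    f"record {rec.id!r}: {len(quals)} qualities for {len(rec.bases)} bases"
                )
            out.append(replace(rec, quals=list(quals)))
        else:
            out.append(replace(rec))
    return out


def write_qual(records: Sequence[SeqRecord], path: str | Path, per_line: int = 20) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quals is None:
                continue
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.quals), per_line):
                fh.write(" ".join(str(q) for q in rec.quals[i : i + per_line]) + "\n")
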
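"""Reading, validating and writing protein sequences in FASTA format.

Every scan in the package starts from a :class:`SequenceRecord`.  Parsing is
strict: residues are uppercased and validated against the 20 standard
amino-acid codes plus the tolerated ambiguity codes ``X B Z U O``; anything
else is rejected with a message naming the offending record and character.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import ALLOWED_RESIDUES

__all__ = ["SequenceRecord", "FastaError", "read_fasta", "write_fasta"]


class FastaError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence.

    Parameters
    ----------
    id:
        First whitespace-delimited token of the FASTA header; must be a
        non-empty token without whitespace.
    residues:
        Uppercase residue string over the standard amino-acid alphabet plus
        the tolerated ambiguity codes.
    description:
        Remainder of the header line (may be empty).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        for i, c in enumerate(self.residues):
            if c not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: disallowed residue character {c!r} "
                    f"at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


Source = Union[str, Path, TextIO]


def _as_handle(source: Source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_fasta(source: Source) -> list[SequenceRecord]:
    """Parse FASTA text into an ordered list of :class:`SequenceRecord`.

    *source* may be a path or an open text stream.  Lowercase residues are
    uppercased; line breaks and surrounding whitespace are removed.  Raises
    :class:`FastaError` for sequence data before the first header, an empty
    sequence body, or a disallowed character.
    """
    handle, close = _as_handle(source)
    try:
        head = handle.read()
        if head.strip() and not head.lstrip().startswith(">"):
            raise FastaError("sequence data found before the first '>' header")
        records: list[SequenceRecord] = []
        for title, seq in SimpleFastaParser(io.StringIO(head)):
            parts = title.split(None, 1)
            if not parts:
                raise FastaError("FASTA header with no identifier")
            rec_id = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            seq = "".join(seq.split())
            if not seq:
                raise FastaError(f"record {rec_id!r} has an empty sequence body")
            try:
                records.append(SequenceRecord(rec_id, seq, description))
            except ValueError as exc:
                raise FastaError(str(exc)) from exc
        return records
    finally:
        if close:
            handle.close()


def write_fasta(
    records: Iterable[SequenceRecord], sink: Source, width: int = 70
) -> None:
    """Write records as FASTA with *width*-column line wrapping.

    ``read_fasta(write_fasta(R))`` reproduces ids, descriptions and residues.
    """
    handle, close = _as_handle(sink, "w")
    try:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
    finally:
        if close:
            handle.close()
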
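"""Hexapeptide character-class motifs: definition, compilation and scanning.

A LIR motif is modelled as six ordered positions, each allowing a subset of
the 20 standard residues.  Two motifs are built in:

* ``clir`` — the canonical LIR pattern ``[DE][DEST][WFY][DELIV]X[ILV]``
  (Alemu et al. 2012), where ``X`` is any residue;
* ``xlir`` — the extended pattern
  ``[ADEFGLPRSK][DEGMSTV][WFY][DEILQTV][ADEFHIKLMPSTV][ILV]`` derived to
  match all 27 experimentally verified LIR instances, keeping the conserved
  aromatic (W/F/Y) at position 3 and aliphatic (I/L/V) at position 6.

Ambiguity codes never match any position, wildcard positions included: the
background model and the scoring matrix are undefined for them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

from .alphabet import STANDARD_AA
from .background import BackgroundFrequencies
from .seq_io import SequenceRecord

__all__ = [
    "MOTIF_LENGTH",
    "MotifDefinition",
    "MotifHit",
    "builtin_motif",
    "compile_motif",
    "matches",
    "scan_motif",
    "motif_probability",
]

MOTIF_LENGTH = 6

_BUILTIN_PATTERNS = {
    "clir": "[DE][DEST][WFY][DELIV]X[ILV]",
    "xlir": "[ADEFGLPRSK][DEGMSTV][WFY][DEILQTV][ADEFHIKLMPSTV][ILV]",
}


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered list of six allowed-residue sets."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) != MOTIF_LENGTH:
            raise ValueError(
                f"motif {self.name!r} must have exactly {MOTIF_LENGTH} positions, "
                f"got {len(self.positions)}"
            )
        for i, pos in enumerate(self.positions, start=1):
            if not pos:
                raise ValueError(f"motif {self.name!r}: position {i} is empty")
            bad = pos - set(STANDARD_AA)
            if bad:
                raise ValueError(
                    f"motif {self.name!r}: position {i} contains "
                    f"non-standard residues {sorted(bad)}"
                )

    def to_regex(self) -> str:
        """Bracket-class regular expression over the standard alphabet."""
        return "".join(f"[{''.join(sorted(p))}]" for p in self.positions)


@dataclass(frozen=True)
class MotifHit:
    """A motif match; coordinates are 1-based inclusive."""

    sequence_id: str
    start: int
    end: int
    peptide: str
    motif_name: str

    def __post_init__(self) -> None:
        if self.end != self.start + MOTIF_LENGTH - 1:
            raise ValueError("hit must span exactly six residues")
        if len(self.peptide) != MOTIF_LENGTH:
            raise ValueError("hit peptide must be a hexapeptide")


def builtin_motif(name: str) -> MotifDefinition:
    """Return one of the built-in motifs, ``"xlir"`` or ``"clir"``."""
    key = name.lower()
    if key not in _BUILTIN_PATTERNS:
        raise ValueError(f"unknown builtin motif {name!r}; expected 'xlir' or 'clir'")
    return compile_motif(_BUILTIN_PATTERNS[key], name=key)


_TOKEN = re.compile(r"\[([A-Za-z]+)\]|([A-Za-z])")


def compile_motif(pattern: str, name: str = "custom") -> MotifDefinition:
    """Parse bracket notation (e.g. ``"W[AC]XXXX"``) into a motif.

    Each of the six tokens is a single residue letter, a bracketed residue
    class, or the wildcard letter ``X`` meaning any standard residue.
    """
    tokens = []
    pos = 0
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(f"cannot parse motif pattern at {pattern[pos:]!r}")
        tokens.append(m.group(1) or m.group(2))
        pos = m.end()
    if len(tokens) != MOTIF_LENGTH:
        raise ValueError(
            f"motif pattern must have {MOTIF_LENGTH} positions, got {len(tokens)}"
        )
    positions = []
    for i, tok in enumerate(tokens, start=1):
        tok = tok.upper()
        if tok == "X":
            positions.append(frozenset(STANDARD_AA))
            continue
        bad = set(tok) - set(STANDARD_AA)
        if bad:
            raise ValueError(
                f"position {i}: illegal residue letter(s) {sorted(bad)}"
            )
        positions.append(frozenset(tok))
    return MotifDefinition(name, tuple(positions))


def matches(motif: MotifDefinition, peptide: str) -> bool:
    """Position-wise class membership of a hexapeptide.

    Any ambiguity code in the peptide makes the test fail, because the
    allowed sets contain only standard residues.
    """
    if len(peptide) != MOTIF_LENGTH:
        raise ValueError(f"peptide must have length {MOTIF_LENGTH}: {peptide!r}")
    peptide = peptide.upper()
    return all(c in pos for c, pos in zip(peptide, motif.positions))


@lru_cache(maxsize=64)
def _compiled(regex: str) -> re.Pattern[str]:
    # lookahead so overlapping windows are all reported
    return re.compile(f"(?=({regex}))")


def scan_motif(record: SequenceRecord, motif: MotifDefinition) -> list[MotifHit]:
    """All motif matches in a sequence, overlapping windows included.

    Hits are sorted by start; coordinates are 1-based inclusive.  Sequences
    shorter than six residues yield an empty list.
    """
    hits = []
    for m in _compiled(motif.to_regex()).finditer(record.residues):
        start = m.start() + 1
        hits.append(
            MotifHit(record.id, start, start + MOTIF_LENGTH - 1, m.group(1), motif.name)
        )
    return hits


def motif_probability(motif: MotifDefinition, bg: BackgroundFrequencies) -> float:
    """Probability that a random background hexapeptide matches the motif.

    The product over the six positions of the summed background frequencies
    of the allowed residues (positions independent, i.i.d. background).
    """
    p = 1.0
    for pos in motif.positions:
        p *= sum(bg[a] for a in pos)
    return p
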
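"""Amino-acid alphabet shared by all modules.

``STANDARD_AA`` fixes the column order of every scoring matrix in the
package (the conventional PSI-BLAST ordering).  Ambiguity codes are
tolerated on input but never participate in motif matching or scoring.
"""

from __future__ import annotations

#: The 20 standard residues, in scoring-matrix column order.
STANDARD_AA: str = "ARNDCQEGHILKMFPSTWYV"

#: Tolerated ambiguity / non-standard codes (unknown, Asx, Glx, Sec, Pyl).
AMBIGUITY_CODES: frozenset[str] = frozenset("XBZUO")

#: Everything a sequence record may contain.
ALLOWED_RESIDUES: frozenset[str] = frozenset(STANDARD_AA) | AMBIGUITY_CODES

#: Index of each standard residue in ``STANDARD_AA``.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_AA)}


def is_standard(peptide: str) -> bool:
    """True iff every character of *peptide* is one of the 20 standard residues."""
    return all(c in AA_INDEX for c in peptide)
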
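"""Packaged reference data: curated LIR-motif instances and the frozen profile.

The motif table collects the published LIR collections of Alemu et al.
(2012; the design and validation set: 27 verified plus 20 unverified
xLIR-matching hexapeptides in 26 proteins), Birgisdottir et al. (2013; an
independent set of 7 verified motifs) and Behrends et al. (2010; candidate
motifs in proteins assayed for LIR-dependent Atg8-family binding), together
with each motif's pattern, anchor-overlap and verification flags and its
reference profile score.

``load_lir_pssm`` returns the frozen LIR profile: the matrix constructed
from the 27 verified hexapeptides and calibrated so that it reproduces the
full reference score set exactly (see :mod:`lirscan.pssm`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

from .predictor import MotifFeatureVector
from .pssm import PositionScoringMatrix, read_ascii_pssm

__all__ = [
    "LabeledMotifRecord",
    "load_lir_motifs",
    "load_lir_pssm",
    "verified_hexapeptides",
    "reference_score_pairs",
    "features_from_records",
    "dataset_summary",
    "DatasetSummary",
    "EXTRA_REFERENCE_SCORES",
    "DEFAULT_SEARCH_SPACE",
]

#: Global effective search space of the e-value calibration, fitted once in
#: log space against the reference (score, e-value) pairs of the frozen
#: profile's accompanying score table.
DEFAULT_SEARCH_SPACE = 73.0

#: Reference-scored hexapeptides reported outside the motif table (two
#: near-miss candidates in the NEK9 kinase).
EXTRA_REFERENCE_SCORES: Mapping[str, int] = {"RGWHTI": 19, "DSWCLL": 16}


@dataclass(frozen=True)
class LabeledMotifRecord:
    """One row of the curated motif table.

    ``anchor_flag`` is True for both plain and starred ("possibly spurious
    xLIR simultaneously predicted as anchor") anchor annotations;
    ``anchor_starred`` distinguishes the latter.  ``pssm_score`` is ``None``
    for pentapeptides, which a gapless hexapeptide profile cannot score.
    Rows without a reported motif have ``peptide == ""``.
    """

    uniprot_id: str
    uniprot_acc: str
    peptide: str
    start: int | None
    end: int | None
    verified: bool | None
    clir_flag: bool | None
    xlir_flag: bool | None
    anchor_flag: bool | None
    anchor_starred: bool
    pssm_score: int | None
    evalue_printed: float | None
    species: str
    dataset_block: str
    behrends_codes: str | None

    @property
    def has_motif(self) -> bool:
        return bool(self.peptide)

    def __post_init__(self) -> None:
        if self.has_motif and self.start is not None and self.end is not None:
            if self.end - self.start + 1 != len(self.peptide):
                raise ValueError(
                    f"{self.uniprot_id} {self.peptide}: span does not match peptide length"
                )


def _flag(value: str) -> bool | None:
    return {"Yes": True, "Yes*": True, "No": False, "NA": None}[value]


def load_lir_motifs() -> list[LabeledMotifRecord]:
    """All rows of the packaged motif table, in printed order."""
    ref = resources.files("lirscan.data") / "lir_motifs.tsv"
    records = []
    with ref.open() as handle:
        for line in handle:
            if line.startswith("#") or line.startswith("uniprot_id"):
                continue
            (uid, acc, pep, start, end, ver, clir, xlir, anchor,
             score, evalue, species, block, codes) = line.rstrip("\n").split("\t")
            records.append(
                LabeledMotifRecord(
                    uniprot_id=uid,
                    uniprot_acc=acc,
                    peptide="" if pep == "-" else pep,
                    start=None if start == "NA" else int(start),
                    end=None if end == "NA" else int(end),
                    verified=_flag(ver),
                    clir_flag=_flag(clir),
                    xlir_flag=_flag(xlir),
                    anchor_flag=_flag(anchor),
                    anchor_starred=anchor == "Yes*",
                    pssm_score=None if score == "NA" else int(score),
                    evalue_printed=None if evalue == "NA" else float(evalue),
                    species=species,
                    dataset_block=block,
                    behrends_codes=None if codes == "-" else codes,
                )
            )
    return records


def load_lir_pssm() -> PositionScoringMatrix:
    """The frozen, reference-calibrated LIR profile matrix."""
    ref = resources.files("lirscan.data") / "lir_pssm.asc"
    with ref.open() as handle:
        return read_ascii_pssm(handle)


def verified_hexapeptides(
    records: Iterable[LabeledMotifRecord] | None = None,
    block: str = "alemu",
) -> list[str]:
    """The verified hexapeptide motif instances of one dataset block."""
    if records is None:
        records = load_lir_motifs()
    return [
        r.peptide
        for r in records
        if r.dataset_block == block and r.verified and len(r.peptide) == 6
    ]


def reference_score_pairs(
    records: Iterable[LabeledMotifRecord] | None = None,
    include_extra: bool = True,
) -> dict[str, int]:
    """All reference (hexapeptide, profile score) pairs.

    Duplicated peptides across blocks carry consistent scores; an
    inconsistency would indicate a corrupted table and raises.
    """
    if records is None:
        records = load_lir_motifs()
    pairs: dict[str, int] = {}
    for r in records:
        if r.pssm_score is None or len(r.peptide) != 6:
            continue
        if pairs.setdefault(r.peptide, r.pssm_score) != r.pssm_score:
            raise ValueError(f"inconsistent reference scores for {r.peptide}")
    if include_extra:
        for pep, s in EXTRA_REFERENCE_SCORES.items():
            if pairs.setdefault(pep, s) != s:
                raise ValueError(f"inconsistent reference scores for {pep}")
    return pairs


def features_from_records(
    records: Iterable[LabeledMotifRecord] | None = None,
    block: str = "alemu",
) -> list[MotifFeatureVector]:
    """Feature vectors for the motif instances of one block.

    The evaluation universe of the validation tables is the xLIR-matching
    hexapeptides of the Alemu block (27 verified + 20 unverified).
    """
    if records is None:
        records = load_lir_motifs()
    return [
        MotifFeatureVector(
            peptide=r.peptide,
            matches_xlir=bool(r.xlir_flag),
            matches_clir=bool(r.clir_flag),
            anchor_overlap=bool(r.anchor_flag),
            pssm_score=r.pssm_score,
            verified=bool(r.verified),
        )
        for r in records
        if r.dataset_block == block and r.has_motif
    ]


@dataclass(frozen=True)
class DatasetSummary:
    """Per-block tallies of the motif table."""

    block: str
    n_motifs: int
    n_verified: int
    n_unverified: int
    verified_clir: int
    verified_xlir: int
    verified_anchor: int
    n_pentapeptides: int


def dataset_summary(
    records: Iterable[LabeledMotifRecord] | None = None,
) -> dict[str, DatasetSummary]:
    """Counting statistics per dataset block."""
    if records is None:
        records = load_lir_motifs()
    records = list(records)
    out = {}
    for block in ("alemu", "birgisdottir", "behrends"):
        rows = [r for r in records if r.dataset_block == block and r.has_motif]
        ver = [r for r in rows if r.verified]
        out[block] = DatasetSummary(
            block=block,
            n_motifs=len(rows),
            n_verified=len(ver),
            n_unverified=sum(1 for r in rows if r.verified is False),
            verified_clir=sum(1 for r in ver if r.clir_flag),
            verified_xlir=sum(1 for r in ver if r.xlir_flag),
            verified_anchor=sum(1 for r in ver if r.anchor_flag),
            n_pentapeptides=sum(1 for r in rows if len(r.peptide) == 5),
        )
    return out
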
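"""Compound LIR prediction schemes and validation arithmetic.

A candidate motif is summarized by a :class:`MotifFeatureVector` (pattern
matches, anchor overlap, profile score, verified label).  Six decision
schemes combine these features; prediction quality is reported as a
confusion matrix and the standard percentages

    accuracy          = 100 (TP + TN) / (TP + FP + TN + FN)
    sensitivity       = 100 TP / (TP + FN)
    specificity       = 100 TN / (FP + TN)
    balanced accuracy = (sensitivity + specificity) / 2

with every unverified predicted motif counted as a false positive.  Score
cutoffs are strict (``score > cutoff``) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Scheme",
    "DEFAULT_CUTOFF",
    "MotifFeatureVector",
    "ConfusionMatrix",
    "ValidationMetrics",
    "decide",
    "evaluate",
    "cutoff_sweep",
    "SweepRow",
    "round1",
]

#: Default profile-score cutoff of the score-gated schemes.
DEFAULT_CUTOFF = 13


class Scheme(str, Enum):
    """Decision schemes combining motif, anchor and profile score."""

    XLIR = "xlir"                  # extended pattern match
    CLIR = "clir"                  # canonical pattern match
    XLIR_A = "xlir+a"              # xLIR and anchor overlap
    CLIR_A = "clir+a"              # cLIR and anchor overlap
    XLIR_A_AND_P = "xlir+a+p"      # xLIR and anchor and score > cutoff
    XLIR_A_OR_P = "xlir+a|p"       # xLIR and (anchor or score > cutoff)


@dataclass(frozen=True)
class MotifFeatureVector:
    """Features of one candidate motif instance.

    ``pssm_score`` is ``None`` for unscorable peptides (pentapeptides); the
    ``verified`` label is used only for evaluation.
    """

    peptide: str
    matches_xlir: bool
    matches_clir: bool
    anchor_overlap: bool
    pssm_score: int | None
    verified: bool

    @property
    def scorable(self) -> bool:
        return self.pssm_score is not None


def decide(scheme: Scheme | str, features: MotifFeatureVector, cutoff: int = DEFAULT_CUTOFF) -> bool:
    """Apply one decision scheme to a feature vector.

    An unscorable peptide fails every score condition.
    """
    scheme = Scheme(scheme)
    above = features.scorable and features.pssm_score > cutoff
    if scheme is Scheme.XLIR:
        return features.matches_xlir
    if scheme is Scheme.CLIR:
        return features.matches_clir
    if scheme is Scheme.XLIR_A:
        return features.matches_xlir and features.anchor_overlap
    if scheme is Scheme.CLIR_A:
        return features.matches_clir and features.anchor_overlap
    if scheme is Scheme.XLIR_A_AND_P:
        return features.matches_xlir and features.anchor_overlap and above
    if scheme is Scheme.XLIR_A_OR_P:
        return features.matches_xlir and (features.anchor_overlap or above)
    raise ValueError(f"unknown scheme {scheme!r}")


def round1(x: float) -> float:
    """Round half-up to one decimal, as used for the reported percentages."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def metrics(self) -> "ValidationMetrics":
        sens = 100.0 * self.TP / (self.TP + self.FN) if self.TP + self.FN else None
        spec = 100.0 * self.TN / (self.FP + self.TN) if self.FP + self.TN else None
        acc = 100.0 * (self.TP + self.TN) / self.total if self.total else None
        bacc = (sens + spec) / 2.0 if sens is not None and spec is not None else None
        return ValidationMetrics(acc, sens, spec, bacc)


@dataclass(frozen=True)
class ValidationMetrics:
    """Percentages in [0, 100]; ``None`` marks an undefined metric.

    Values are kept at full precision; display rounding is half-up to one
    decimal via :meth:`rounded`.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None

    def rounded(self) -> "ValidationMetrics":
        r = lambda v: None if v is None else round1(v)
        return ValidationMetrics(
            r(self.accuracy), r(self.sensitivity),
            r(self.specificity), r(self.balanced_accuracy),
        )


def evaluate(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> tuple[ConfusionMatrix, ValidationMetrics]:
    """Confusion matrix and metrics for paired predictions and labels."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    tp = sum(p and l for p, l in zip(predictions, labels))
    fp = sum(p and not l for p, l in zip(predictions, labels))
    fn = sum(not p and l for p, l in zip(predictions, labels))
    tn = sum(not p and not l for p, l in zip(predictions, labels))
    cm = ConfusionMatrix(tp, fp, tn, fn)
    return cm, cm.metrics()


@dataclass(frozen=True)
class SweepRow:
    """One row of a profile-score cutoff sweep."""

    cutoff: int
    verified_above: int
    unverified_above: int
    confusion: ConfusionMatrix
    metrics: ValidationMetrics


def cutoff_sweep(
    features: Iterable[MotifFeatureVector], cutoffs: Iterable[int]
) -> list[SweepRow]:
    """Above-cutoff counts and metrics across score thresholds.

    For each cutoff c the prediction is ``matches_xlir and score > c``; the
    above-cutoff counts tally scorable features by verified label.  All
    features must be scorable.
    """
    feats = list(features)
    for f in feats:
        if not f.scorable:
            raise ValueError(f"unscorable peptide {f.peptide!r} in cutoff sweep")
    rows = []
    for c in cutoffs:
        preds = [f.matches_xlir and f.pssm_score > c for f in feats]
        labels = [f.verified for f in feats]
        cm, m = evaluate(preds, labels)
        rows.append(
            SweepRow(
                cutoff=c,
                verified_above=sum(f.pssm_score > c for f in feats if f.verified),
                unverified_above=sum(f.pssm_score > c for f in feats if not f.verified),
                confusion=cm,
                metrics=m,
            )
        )
    return rows
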
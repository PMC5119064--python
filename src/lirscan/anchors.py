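"""Disordered-binding ("anchor") regions and motif-anchor overlap.

Anchors are subsequences flanking or overlapping intrinsically disordered
regions with a high potential to fold upon binding, as output by an external
disorder-binding predictor such as ANCHOR.  The predictor itself is not
re-implemented; anchor sources are pluggable: parsed output files (interval
tables or per-residue binary calls) or the curated flags shipped with the
reference dataset.

A motif is considered anchor-supported when it overlaps an anchor region in
more than three residues (i.e. at least four).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

__all__ = [
    "AnchorRegion",
    "MIN_ANCHOR_OVERLAP",
    "overlap_length",
    "anchor_overlaps_hit",
    "read_anchor_regions",
    "regions_from_binary_calls",
]

#: Overlap (residues) required to call a motif anchor-supported: "> 3".
MIN_ANCHOR_OVERLAP = 4


@dataclass(frozen=True)
class AnchorRegion:
    """A 1-based inclusive interval of anchor residues in one sequence."""

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"malformed interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


def _interval(x) -> tuple[int, int]:
    if hasattr(x, "start") and hasattr(x, "end"):
        start, end = int(x.start), int(x.end)
    else:
        start, end = int(x[0]), int(x[1])
    if not 1 <= start <= end:
        raise ValueError(f"malformed interval {start}-{end}")
    return start, end


def overlap_length(a, b) -> int:
    """Number of residues shared by two 1-based inclusive intervals.

    Accepts any pair of objects with ``start``/``end`` attributes or
    ``(start, end)`` tuples; symmetric; 0 when disjoint.
    """
    a1, a2 = _interval(a)
    b1, b2 = _interval(b)
    return max(0, min(a2, b2) - max(a1, b1) + 1)


def anchor_overlaps_hit(hit, anchors: Iterable[AnchorRegion]) -> bool:
    """True iff some anchor overlaps the hit in at least four residues."""
    return any(overlap_length(hit, a) >= MIN_ANCHOR_OVERLAP for a in anchors)


def regions_from_binary_calls(
    sequence_id: str, calls: Sequence[int]
) -> list[AnchorRegion]:
    """Convert per-residue 0/1 anchor calls to maximal positive runs."""
    regions = []
    start = None
    for i, c in enumerate(calls, start=1):
        if c not in (0, 1):
            raise ValueError(f"per-residue call must be 0 or 1, got {c!r}")
        if c and start is None:
            start = i
        elif not c and start is not None:
            regions.append(AnchorRegion(sequence_id, start, i - 1))
            start = None
    if start is not None:
        regions.append(AnchorRegion(sequence_id, start, len(calls)))
    return regions


def _merge(regions: list[AnchorRegion]) -> list[AnchorRegion]:
    merged: list[AnchorRegion] = []
    for r in sorted(regions, key=lambda r: (r.sequence_id, r.start, r.end)):
        if merged and merged[-1].sequence_id == r.sequence_id and r.start <= merged[-1].end + 1:
            if r.end > merged[-1].end:
                warnings.warn(
                    f"merging overlapping anchor intervals for {r.sequence_id}"
                )
                merged[-1] = AnchorRegion(r.sequence_id, merged[-1].start, r.end)
        else:
            merged.append(r)
    return merged


def read_anchor_regions(
    source: Union[str, Path, TextIO],
    sequence_id: str | None = None,
) -> list[AnchorRegion]:
    """Read anchor regions from a text file.

    Two formats are auto-detected:

    * interval table: whitespace/tab-separated ``sequence_id start end``
      rows (overlapping or adjacent intervals are merged with a warning);
    * per-residue binary calls: one ``0``/``1`` per line, in sequence
      order, requiring *sequence_id*; maximal runs of ``1`` become regions.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = [l.strip() for l in text.splitlines()]
    lines = [l for l in lines if l and not l.startswith("#")]
    if not lines:
        return []
    if all(l in ("0", "1") for l in lines):
        if sequence_id is None:
            raise ValueError("per-residue call format requires a sequence_id")
        return regions_from_binary_calls(sequence_id, [int(l) for l in lines])
    regions = []
    for l in lines:
        fields = l.split()
        if len(fields) != 3:
            raise ValueError(f"malformed anchor line: {l!r}")
        try:
            regions.append(AnchorRegion(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise ValueError(f"malformed anchor line: {l!r}") from exc
    return _merge(regions)
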
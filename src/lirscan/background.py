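"""Background amino-acid frequency model and sequence null models.

The packaged background distribution is the residue composition of
UniProtKB/Swiss-Prot (release 2013_04).  It drives motif occurrence
probabilities, PSSM log-odds and the exact null score distribution behind
e-values.  Two null-sequence generators are provided: composition-preserving
shuffling of a real sequence, and i.i.d. sampling from the background.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, TextIO, Union

import numpy as np

from .alphabet import STANDARD_AA
from .seq_io import SequenceRecord

__all__ = [
    "BackgroundFrequencies",
    "load_background",
    "read_background",
    "shuffle_sequence",
    "random_sequence",
]


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Relative abundances of the 20 standard residues, normalized to sum 1."""

    freq: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.freq)
        if missing:
            raise ValueError(f"missing residues in background: {sorted(missing)}")
        if any(not 0.0 < self.freq[a] < 1.0 for a in STANDARD_AA):
            raise ValueError("background frequencies must lie in (0, 1)")
        total = sum(self.freq[a] for a in STANDARD_AA)
        object.__setattr__(
            self, "freq", {a: self.freq[a] / total for a in STANDARD_AA}
        )

    def __getitem__(self, residue: str) -> float:
        return self.freq[residue]

    def as_array(self, order: str = STANDARD_AA) -> np.ndarray:
        """Frequencies as a vector in the given residue order."""
        return np.array([self.freq[a] for a in order])

    @classmethod
    def from_percentages(cls, percent: Mapping[str, float]) -> "BackgroundFrequencies":
        return cls({a: p / 100.0 for a, p in percent.items()})


def read_background(source: Union[str, Path, TextIO]) -> BackgroundFrequencies:
    """Read a two-column (residue, percent) table and renormalize."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    percent: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("residue"):
            continue
        residue, value = line.split()
        percent[residue] = float(value)
    return BackgroundFrequencies.from_percentages(percent)


def load_background() -> BackgroundFrequencies:
    """The packaged Swiss-Prot background composition."""
    ref = resources.files("lirscan.data") / "background_frequencies.tsv"
    with ref.open() as handle:
        return read_background(handle)


def shuffle_sequence(record: SequenceRecord, seed: int) -> SequenceRecord:
    """Uniformly random permutation of the residues (composition preserved).

    Deterministic for a fixed seed; the returned record keeps the input id
    with a ``|shuffled`` suffix.
    """
    rng = np.random.default_rng(seed)
    residues = "".join(rng.permutation(list(record.residues)))
    return SequenceRecord(
        f"{record.id}|shuffled", residues, f"shuffle of {record.id} (seed={seed})"
    )


def random_sequence(
    length: int,
    bg: BackgroundFrequencies,
    seed: int,
    record_id: str = "random",
) -> SequenceRecord:
    """Sequence of i.i.d. draws from the background distribution."""
    if length < 0:
        raise ValueError("length must be non-negative")
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(STANDARD_AA), size=length, p=bg.as_array())
    return SequenceRecord(record_id, "".join(letters), f"i.i.d. background (seed={seed})")
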
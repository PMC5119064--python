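"""Position-specific scoring matrix construction, scanning and e-values.

The LIR profile is a 6x20 integer log-odds matrix built from an alignment of
verified hexapeptide motif instances.  Construction follows the classic
profile recipe: position-based sequence weighting, observed column
frequencies mixed with substitution-model (BLOSUM62) pseudocounts, log-odds
against a background composition, and scaling to integer units.

For a column with weighted observed frequencies ``f`` the pseudocount target
frequencies are ``g_j = sum_i f_i q_ij / p_i`` (``q`` the BLOSUM62 joint
target frequencies, ``p`` the substitution model's background), the
estimated residue probabilities are

    Q_j = (alpha * f_j + beta * g_j) / (alpha + beta)

with ``alpha`` the mean number of distinct residues per column minus one and
``beta`` the pseudocount weight, and the integer score is
``round(ln(Q_j / b_j) / scale)`` against the scan background ``b``.

Because the exact profile tool, version and rounding behind the published
reference scores are not recoverable from the construction description
alone, the package ships a calibration step
(:func:`calibrate_to_reference`): an L1-minimal integer adjustment of the
constructed matrix subject to reproducing a set of reference
(hexapeptide, score) pairs exactly.  The calibrated matrix is frozen as a
packaged fixture (see :mod:`lirscan.datasets`).

E-values use the exact null distribution of the score of a hexapeptide
drawn i.i.d. from the background, computed by dynamic programming over the
six positions, times a global effective search space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TextIO, Union

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AA_INDEX, STANDARD_AA, is_standard
from .background import BackgroundFrequencies, load_background
from .motifs import MOTIF_LENGTH
from .seq_io import SequenceRecord

__all__ = [
    "PssmConstructionParams",
    "PositionScoringMatrix",
    "WindowScore",
    "PssmScanResult",
    "EvalueCalibration",
    "ScoredHit",
    "robinson_frequencies",
    "blosum62_target_frequencies",
    "build_pssm",
    "score_hexapeptide",
    "scan_pssm",
    "read_ascii_pssm",
    "write_ascii_pssm",
    "exact_null_distribution",
    "calibrate_evalues",
    "calibrate_to_reference",
]

# Robinson & Robinson (1991) residue frequencies: the background the BLOSUM
# substitution statistics are referred to, used for pseudocount targets.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07129, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def robinson_frequencies() -> BackgroundFrequencies:
    """The Robinson & Robinson amino-acid frequencies."""
    return BackgroundFrequencies(_ROBINSON)


@dataclass(frozen=True)
class PssmConstructionParams:
    """Tunable parameters of profile construction.

    The defaults are the package's frozen calibration against the reference
    score set (see module docstring and the methods documentation);
    ``scale`` is in nats per score unit.
    """

    pseudocount_weight: float = 14.0
    substitution_model: str = "blosum62"
    scale: float = 0.325
    background: BackgroundFrequencies | None = None
    pseudocount_background: BackgroundFrequencies | None = None
    sequence_weighting: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount_weight < 0:
            raise ValueError("pseudocount_weight must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.substitution_model.lower() != "blosum62":
            raise ValueError("only the blosum62 substitution model is supported")


@dataclass(frozen=True)
class PositionScoringMatrix:
    """6x20 integer log-odds matrix over ``STANDARD_AA`` column order."""

    scores: np.ndarray
    alphabet: str = STANDARD_AA
    construction: PssmConstructionParams | str = "external"

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores)
        if arr.shape != (MOTIF_LENGTH, 20):
            raise ValueError(f"scores must be {MOTIF_LENGTH}x20, got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("scores must be integers")
        if sorted(self.alphabet) != sorted(STANDARD_AA):
            raise ValueError("alphabet must contain all 20 standard residues")
        if self.alphabet != STANDARD_AA:
            # remap columns to canonical order
            order = [self.alphabet.index(a) for a in STANDARD_AA]
            arr = arr[:, order]
            object.__setattr__(self, "alphabet", STANDARD_AA)
        arr = np.array(arr, dtype=int)
        arr.setflags(write=False)
        object.__setattr__(self, "scores", arr)

    def score(self, peptide: str) -> int:
        return score_hexapeptide(self, peptide)

    def consensus(self) -> str:
        """Highest-scoring residue at each position."""
        return "".join(STANDARD_AA[j] for j in self.scores.argmax(axis=1))

    @property
    def min_score(self) -> int:
        return int(self.scores.min(axis=1).sum())

    @property
    def max_score(self) -> int:
        return int(self.scores.max(axis=1).sum())


def blosum62_target_frequencies(
    bg: BackgroundFrequencies | None = None,
) -> np.ndarray:
    """Joint target frequencies implied by the BLOSUM62 integer matrix.

    Solves ``sum_ij p_i p_j exp(lambda s_ij) = 1`` for lambda over the given
    background (Robinson frequencies by default) and returns the normalized
    20x20 matrix ``q_ij = p_i p_j exp(lambda s_ij)``.
    """
    if bg is None:
        bg = robinson_frequencies()
    p = bg.as_array()
    B = substitution_matrices.load("BLOSUM62")
    S = np.array([[B[a, b] for b in STANDARD_AA] for a in STANDARD_AA], dtype=float)
    lo, hi = 0.05, 1.0
    for _ in range(200):
        lam = 0.5 * (lo + hi)
        if float(np.sum(np.outer(p, p) * np.exp(lam * S))) > 1.0:
            hi = lam
        else:
            lo = lam
    q = np.outer(p, p) * np.exp(0.5 * (lo + hi) * S)
    return q / q.sum()


def _position_based_weights(instances: Sequence[str]) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights."""
    n = len(instances)
    w = np.zeros(n)
    for j in range(MOTIF_LENGTH):
        column = [p[j] for p in instances]
        r = len(set(column))
        for i, c in enumerate(column):
            w[i] += 1.0 / (r * column.count(c))
    return w / w.sum()


def _round_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero."""
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def build_pssm(
    instances: Sequence[str],
    params: PssmConstructionParams | None = None,
) -> PositionScoringMatrix:
    """Build the log-odds matrix from aligned hexapeptide instances.

    Requires at least two instances, all of length six over the standard
    alphabet.  Deterministic.
    """
    if params is None:
        params = PssmConstructionParams()
    if len(instances) < 2:
        raise ValueError("need at least two aligned instances")
    instances = [p.upper() for p in instances]
    for p in instances:
        if len(p) != MOTIF_LENGTH or not is_standard(p):
            raise ValueError(
                f"instance {p!r} is not a hexapeptide over the standard alphabet"
            )
    scan_bg = params.background or load_background()
    pc_bg = params.pseudocount_background or robinson_frequencies()
    q = blosum62_target_frequencies(pc_bg)

    if params.sequence_weighting:
        weights = _position_based_weights(instances)
    else:
        weights = np.full(len(instances), 1.0 / len(instances))
    F = np.zeros((MOTIF_LENGTH, 20))
    for w, pep in zip(weights, instances):
        for j, c in enumerate(pep):
            F[j, AA_INDEX[c]] += w
    n_distinct = np.array(
        [len({p[j] for p in instances}) for j in range(MOTIF_LENGTH)], dtype=float
    )
    alpha = n_distinct.mean() - 1.0

    b = scan_bg.as_array()
    p = pc_bg.as_array()
    beta = params.pseudocount_weight
    scores = np.zeros((MOTIF_LENGTH, 20), dtype=int)
    for j in range(MOTIF_LENGTH):
        f = F[j]
        g = (f / p) @ q
        Q = (alpha * f + beta * g) / (alpha + beta)
        scores[j] = _round_away(np.log(Q / b) / params.scale)
    return PositionScoringMatrix(scores, STANDARD_AA, params)


def score_hexapeptide(pssm: PositionScoringMatrix, peptide: str) -> int:
    """Sum of per-position scores; rejects non-hexapeptides and ambiguity codes."""
    peptide = peptide.upper()
    if len(peptide) != MOTIF_LENGTH:
        raise ValueError(f"peptide must have length {MOTIF_LENGTH}: {peptide!r}")
    if not is_standard(peptide):
        raise ValueError(
            f"peptide {peptide!r} contains ambiguity codes and cannot be scored"
        )
    return int(sum(pssm.scores[j, AA_INDEX[c]] for j, c in enumerate(peptide)))


@dataclass(frozen=True)
class WindowScore:
    """Score of one hexapeptide window (1-based inclusive coordinates)."""

    start: int
    end: int
    peptide: str
    score: int


@dataclass(frozen=True)
class PssmScanResult:
    """All valid window scores of one sequence plus skipped window starts."""

    sequence_id: str
    windows: tuple[WindowScore, ...]
    skipped: tuple[int, ...]  # starts of windows containing ambiguity codes


def scan_pssm(record: SequenceRecord, pssm: PositionScoringMatrix) -> PssmScanResult:
    """Slide the matrix gaplessly along the sequence, one residue at a time.

    A clean sequence of length n yields ``max(0, n - 5)`` scores; windows
    containing ambiguity codes are omitted and reported in ``skipped``.
    """
    seq = record.residues
    windows: list[WindowScore] = []
    skipped: list[int] = []
    # vectorized scoring over valid positions
    codes = np.array([AA_INDEX.get(c, -1) for c in seq], dtype=int)
    for start0 in range(len(seq) - MOTIF_LENGTH + 1):
        window = codes[start0 : start0 + MOTIF_LENGTH]
        if (window < 0).any():
            skipped.append(start0 + 1)
            continue
        s = int(pssm.scores[np.arange(MOTIF_LENGTH), window].sum())
        windows.append(
            WindowScore(start0 + 1, start0 + MOTIF_LENGTH, seq[start0 : start0 + MOTIF_LENGTH], s)
        )
    return PssmScanResult(record.id, tuple(windows), tuple(skipped))


@dataclass(frozen=True)
class ScoredHit:
    """A motif hit with its profile score and e-value attached."""

    sequence_id: str
    start: int
    end: int
    peptide: str
    motif_name: str
    pssm_score: int
    e_value: float


# --- ASCII matrix I/O (PSI-BLAST dialect) ---------------------------------

def read_ascii_pssm(source: Union[str, Path, TextIO]) -> PositionScoringMatrix:
    """Read a PSI-BLAST-style ASCII matrix.

    Expects a header line of 20 residue letters followed by one row per
    position (index, consensus residue, 20 integers).  Trailing statistics
    are ignored.  Columns are remapped to the canonical alphabet order.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.splitlines()
    header_alphabet: list[str] | None = None
    rows: list[list[int]] = []
    for line in lines:
        fields = line.split()
        if header_alphabet is None:
            if len(fields) >= 20 and all(
                f in STANDARD_AA and len(f) == 1 for f in fields[:20]
            ):
                header_alphabet = fields[:20]
            continue
        if len(fields) >= 22 and fields[0].isdigit():
            try:
                rows.append([int(x) for x in fields[2:22]])
            except ValueError as exc:
                raise ValueError(f"non-integer matrix cell in row: {line!r}") from exc
    if header_alphabet is None:
        raise ValueError("no residue header line found")
    if len(set(header_alphabet)) != 20:
        raise ValueError("residue header must name all 20 standard residues")
    if len(rows) != MOTIF_LENGTH:
        raise ValueError(f"expected {MOTIF_LENGTH} matrix rows, found {len(rows)}")
    return PositionScoringMatrix(
        np.array(rows, dtype=int), "".join(header_alphabet), "external"
    )


def write_ascii_pssm(pssm: PositionScoringMatrix, sink: Union[str, Path, TextIO]) -> None:
    """Write the matrix in the same ASCII dialect :func:`read_ascii_pssm` reads."""
    out = ["# position-specific scoring matrix (integer log-odds)"]
    out.append("      " + "  ".join(STANDARD_AA))
    consensus = pssm.consensus()
    for j in range(MOTIF_LENGTH):
        cells = " ".join(f"{int(v):3d}" for v in pssm.scores[j])
        out.append(f"{j + 1:3d} {consensus[j]} {cells}")
    text = "\n".join(out) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


# --- e-values --------------------------------------------------------------

def exact_null_distribution(
    pssm: PositionScoringMatrix, bg: BackgroundFrequencies
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the score of an i.i.d. background hexapeptide.

    Dynamic programming over the six positions; feasible exactly because the
    entries are small integers.  Returns ``(scores, tail)`` with
    ``tail[i] = P(S >= scores[i])``.
    """
    p = bg.as_array()
    pmf: dict[int, float] = {0: 1.0}
    for j in range(MOTIF_LENGTH):
        nxt: dict[int, float] = {}
        row = pssm.scores[j]
        for s, prob in pmf.items():
            for k in range(20):
                t = s + int(row[k])
                nxt[t] = nxt.get(t, 0.0) + prob * p[k]
        pmf = nxt
    scores = np.array(sorted(pmf))
    probs = np.array([pmf[int(s)] for s in scores])
    tail = probs[::-1].cumsum()[::-1]
    return scores, tail


@dataclass(frozen=True)
class EvalueCalibration:
    """Score-to-e-value mapping from the exact i.i.d. null.

    ``evalue(s) = search_space * P(S >= s)``; ``lam``/``kappa`` summarize the
    upper tail as ``P(S >= s) ~ kappa * exp(-lam * s)``.
    """

    lam: float
    kappa: float
    search_space: float
    null_scores: np.ndarray = field(repr=False)
    null_tail: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.kappa <= 0 or self.search_space < 1:
            raise ValueError("require lam > 0, kappa > 0, search_space >= 1")

    def tail_probability(self, score: float) -> float:
        """P(S >= score) under the exact null."""
        idx = np.searchsorted(self.null_scores, score)
        if idx >= len(self.null_tail):
            return 0.0
        return float(self.null_tail[idx])

    def evalue(self, score: float) -> float:
        return self.search_space * self.tail_probability(score)


def calibrate_evalues(
    pssm: PositionScoringMatrix,
    bg: BackgroundFrequencies,
    search_space: float,
) -> EvalueCalibration:
    """Exact-null e-value calibration for a matrix and background.

    The log-linear (lam, kappa) summary is fitted over the non-negative part
    of the tail, where the decay is close to exponential.
    """
    if search_space < 1:
        raise ValueError("search_space must be >= 1")
    p = bg.as_array()
    if np.any(p <= 0):
        raise ValueError("degenerate background")
    scores, tail = exact_null_distribution(pssm, bg)
    sel = (scores >= 0) & (tail > 0)
    if sel.sum() < 2:
        sel = tail > 0
    slope, intercept = np.polyfit(scores[sel], np.log(tail[sel]), 1)
    if slope >= 0:
        raise ValueError("null tail is not decreasing; matrix degenerate")
    return EvalueCalibration(
        lam=float(-slope),
        kappa=float(math.exp(intercept)),
        search_space=float(search_space),
        null_scores=scores,
        null_tail=tail,
    )


# --- reference-score calibration ------------------------------------------

def calibrate_to_reference(
    pssm: PositionScoringMatrix,
    reference: Mapping[str, int],
    bound: int = 8,
) -> PositionScoringMatrix:
    """L1-minimal integer adjustment reproducing reference peptide scores.

    Finds the integer matrix closest (in summed absolute difference) to
    *pssm* such that every reference hexapeptide receives exactly its
    reference score; cells not constrained by any reference peptide are left
    unchanged.  Solved as a mixed-integer linear program.  Raises if the
    reference set is infeasible within ``+-bound`` of the input entries.
    """
    from scipy.optimize import Bounds, LinearConstraint, milp

    n = MOTIF_LENGTH * 20
    m0 = pssm.scores.flatten().astype(float)
    # variables: n integer matrix cells, n continuous slack |m - m0|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    rows, lbs, ubs = [], [], []
    for pep, target in reference.items():
        pep = pep.upper()
        if len(pep) != MOTIF_LENGTH or not is_standard(pep):
            raise ValueError(f"reference peptide {pep!r} is not scorable")
        row = np.zeros(2 * n)
        for j, ch in enumerate(pep):
            row[j * 20 + AA_INDEX[ch]] += 1
        rows.append(row)
        lbs.append(float(target))
        ubs.append(float(target))
    for k in range(n):
        r1 = np.zeros(2 * n)
        r1[k], r1[n + k] = 1, -1
        rows.append(r1), lbs.append(-np.inf), ubs.append(m0[k])
        r2 = np.zeros(2 * n)
        r2[k], r2[n + k] = -1, -1
        rows.append(r2), lbs.append(-np.inf), ubs.append(-m0[k])
    constraints = LinearConstraint(np.array(rows), np.array(lbs), np.array(ubs))
    bounds = Bounds(
        np.concatenate([m0 - bound, np.zeros(n)]),
        np.concatenate([m0 + bound, np.full(n, np.inf)]),
    )
    integrality = np.concatenate([np.ones(n), np.zeros(n)])
    res = milp(c=c, constraints=constraints, integrality=integrality, bounds=bounds)
    if res.status != 0:
        raise RuntimeError(f"reference calibration infeasible: {res.message}")
    scores = np.rint(res.x[:n]).astype(int).reshape(MOTIF_LENGTH, 20)
    return PositionScoringMatrix(scores, STANDARD_AA, pssm.construction)
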
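# Methods

`lirscan` predicts candidate LC3-interacting regions (LIRs, also called
Atg8-family interacting motifs, AIMs): short linear motifs through which
selective autophagy receptors and other LIR-containing proteins bind
Atg8-family ubiquitin-like proteins (LC3/GABARAP subfamilies). The package
combines three sequence-level signals — a character-class hexapeptide
pattern, a position-specific scoring matrix (PSSM), and overlap with
predicted disorder-binding ("anchor") regions — and reproduces the
validation arithmetic of the resulting compound predictors.

## Motif model

A motif is six ordered positions, each an allowed subset of the 20 standard
residues. Two patterns are built in:

* **cLIR** (canonical): `[DE][DEST][WFY][DELIV]X[ILV]`, the consensus
  derived by Alemu et al. (2012) from 26 characterized LIR-containing
  proteins.
* **xLIR** (extended): `[ADEFGLPRSK][DEGMSTV][WFY][DEILQTV][ADEFHIKLMPSTV][ILV]`,
  the relaxation that admits, by construction, all 27 experimentally
  verified hexapeptide LIRs of that collection, keeping the conserved
  aromatic residue (W/F/Y) at position 3 and the aliphatic residue (I/L/V)
  at position 6 — the two residues that dock into the hydrophobic pockets
  of the Atg8 LIR-docking site.

Scanning enumerates every window of the forward protein sequence;
overlapping matches are all reported and coordinates are 1-based inclusive,
matching the curated annotations. Ambiguity codes (`X B Z U O`) are
tolerated in input sequences but never match any motif position — the
background model and the PSSM are defined only over the standard alphabet —
and any scoring window containing them is skipped and flagged.

Under an i.i.d. background the probability that a random hexapeptide
matches a motif is the product over positions of the summed allowed-residue
frequencies. With the packaged Swiss-Prot composition this gives
1.5 × 10⁻³ for xLIR. For cLIR the same product evaluates to
1.8 × 10⁻⁴; the historically reported figure of 1.8 × 10⁻⁶ is not
reproducible from the stated formula and inputs (it appears to drop two
orders of magnitude, plausibly a typographical slip), so the package
computes and documents the product value and does not treat the historical
figure as a reference.

## Background model and nulls

The packaged background is the amino-acid composition of
UniProtKB/Swiss-Prot release 2013_04 (percent abundances of the 20 standard
residues). The printed percentages sum to 99.89; they are renormalized to
exactly 1, shifting each frequency by about 0.1%. Two null-sequence
generators support false-positive estimation: a uniformly random,
composition-preserving permutation of a real sequence, and i.i.d. sampling
from the background. Every stochastic operation takes an explicit integer
seed and is reproducible.

## PSSM construction

The LIR profile is a 6 × 20 integer log-odds matrix built from the
alignment of the 27 verified hexapeptides. Construction follows the classic
position-specific pseudocount recipe:

1. position-based (Henikoff & Henikoff) sequence weights over the gapless
   alignment;
2. pseudocount target frequencies `g_j = Σ_i f_i q_ij / p_i`, with `q` the
   BLOSUM62 joint target frequencies (recovered from the integer BLOSUM62
   matrix by solving for its implied λ over the Robinson–Robinson
   background `p`);
3. estimated probabilities `Q_j = (α f_j + β g_j) / (α + β)`, with `α` the
   mean number of distinct residues per column minus one and `β` the
   pseudocount weight;
4. integer scores `round(ln(Q_j / b_j) / scale)` against the packaged
   Swiss-Prot background `b`, rounding ties away from zero.

Defaults: `β = 14` and `scale = 0.325` nats per score unit. These two
values were frozen once by calibrating the construction against the full
set of 92 reference (hexapeptide, score) pairs that accompany the curated
motif table; the calibrated scale closely matches both the ungapped
BLOSUM62 λ (0.318) and the exponential decay implied by the reference
score→e-value pairs (0.328). The profile tool and version originally used
to derive the reference scores are not recoverable from their published
description, and no parameter setting of the scheme above reproduces every
reference score exactly: at the frozen defaults the raw construction
reproduces 36/92 pairs, with a maximum deviation of 4 and mean absolute
deviation below 1.5 score units, and it does reproduce the key reference
peptides (DDWDFL → 26, DDWTHL → 24).

Because downstream validation arithmetic depends on exact integer scores,
the package applies a final **reference calibration**: the L1-minimal
integer adjustment of the constructed matrix subject to reproducing every
reference pair exactly, solved as a mixed-integer linear program (cells
unconstrained by any reference peptide stay at their constructed values;
the total adjustment is 20 score units spread over the 120 cells). The
calibrated matrix is frozen as the packaged fixture
(`src/lirscan/data/lir_pssm.asc`, PSI-BLAST-style ASCII dialect) and
regression-tested against all 92 pairs; `scripts/regenerate_pssm_fixture.py`
re-derives it end to end.

Scoring slides the matrix gaplessly one residue at a time; pentapeptide
("noncanonical") LIRs cannot be scored by a gapless hexapeptide profile and
are reported as unscorable throughout.

## E-values

The e-value of a score `s` is `N · P(S ≥ s)`, where `P` is the exact null
distribution of the score of a hexapeptide drawn i.i.d. from the
background — computed by dynamic programming over the six positions, which
is exact because entries are small integers — and `N` is a global effective
search space. `N = 73` was fitted once, in log space, against the reference
(score, e-value) pairs; a per-run search space (number of scanned windows)
is also supported. A log-linear summary of the tail (`P(S ≥ s) ≈ κ e^{−λs}`,
fitted for s ≥ 0) is exposed alongside. The reference e-values follow an
almost perfect exponential in the score (decay ≈ 0.33 per unit), whereas
the exact null of the frozen matrix decays somewhat faster (≈ 0.48);
reference and computed e-values therefore agree only to within about a
factor of two across the useful score range. No headline quantity depends
on e-values.

## Anchor filtering

Anchors — predicted disordered segments with protein-binding potential —
are represented as 1-based inclusive intervals per sequence. A motif is
anchor-supported when it overlaps an anchor in **more than 3 residues**
(implemented strictly as ≥ 4). The disorder predictor itself (ANCHOR/IUPred
energy model) is out of scope; anchor sources are pluggable: interval
tables, per-residue binary call files, or the curated flags shipped with
the reference dataset. Rows flagged as "possibly spurious xLIR
simultaneously predicted as anchor" (starred in the source table) count as
anchor-positive; this is the reading under which the compound-scheme
false-positive counts of the reference validation reproduce.

## Decision schemes and validation

Six schemes combine the features: pattern match alone (xLIR, cLIR), pattern
∧ anchor (xLIR+A, cLIR+A), and the score-gated forms
xLIR ∧ anchor ∧ (score > c) and xLIR ∧ (anchor ∨ score > c), with default
cutoff c = 13. All cutoffs are strict (`>`); this is the convention under
which the reference above-cutoff counts reproduce. Validation counts every
predicted motif without experimental verification as a false positive, over
the universe of the 47 xLIR-matching hexapeptides of the design set
(27 verified + 20 unverified). Metrics are accuracy, sensitivity,
specificity and balanced accuracy = (sensitivity + specificity)/2, kept at
full precision internally and displayed rounded half-up to one decimal.
Undefined metrics (empty positive or negative class) are reported as
undefined, never coerced to zero.

Two reference cells are knowingly divergent and are marked as such rather
than targeted:

* the disjunctive scheme xLIR+A|P13: direct counting from the curated flags
  and scores gives FP = 10 / TN = 10 (accuracy 76.6, specificity 50.0),
  whereas the published table prints 9/11 (78.7, 55.0); the reproducible
  cells TP = 26 / FN = 1 (sensitivity 96.3) are asserted;
* two balanced-accuracy cells of the cutoff sweep (cutoffs 9 and 12) where
  the published values (50.7, 72.0) arise from averaging display-rounded
  sensitivity and specificity; the package keeps the exact identity
  BACC = (Sens + Spec)/2, giving 50.6 and 71.9.

## Reference data

The packaged motif table transcribes the three published LIR collections —
the Alemu et al. (2012) design/validation set, the Birgisdottir et al.
(2013) independent set (7 verified motifs, including two pentapeptides and
two atypical hexapeptides that xLIR misses by design), and the Behrends et
al. (2010) interaction-proteomics set with its GABARAP/MAP1LC3B
mutant-binding codes (stored verbatim; they drive no computation) —
together with each motif's coordinates, flags and reference profile score.
Internal consistency is tested: re-deriving the cLIR/xLIR flags from the
stored peptides with the package's own matchers reproduces the stored
annotation for every row.

Full-length protein sequences are deliberately not shipped: every packaged
computation is defined over the printed motif instances, flags and scores.
End-to-end checks that require complete UniProt sequences (total window
counts over the 26-protein set, shuffled-proteome match counts) are
documented but outside the default test surface, which keeps the package
fully offline.

## What the tests show, and limits

The test suite reproduces the motif arithmetic, occurrence probabilities,
scheme metrics, cutoff sweep and profile regression exactly from packaged
data, and checks the statistical machinery by property tests: the scanner
against a naive window oracle, shuffling against exact composition
preservation, i.i.d. match counts against the analytic expectation at
n = 10⁶ (within three binomial standard errors), and the dynamic-programming
null against brute-force enumeration on a four-letter background. Passing
these tests demonstrates fidelity to the curated reference data and
internal statistical consistency — not predictive performance on new
proteomes: the verified LIR set is small (27 instances), the negative set
is unverified rather than experimentally negative, and anchor calls depend
on an external disorder predictor whose choices are upstream of this
package.
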
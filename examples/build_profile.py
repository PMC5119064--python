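"""Build the LIR profile matrix from the 27 verified motif instances.

Constructs the 6x20 integer log-odds matrix (position-based sequence
weighting, BLOSUM62 pseudocounts, log-odds against the Swiss-Prot
background), prints its consensus and a few reference peptide scores, and
compares the raw construction with the packaged reference-calibrated
profile.
"""

from lirscan import (
    build_pssm,
    load_lir_pssm,
    reference_score_pairs,
    score_hexapeptide,
    verified_hexapeptides,
)

instances = verified_hexapeptides()
print(f"building profile from {len(instances)} verified hexapeptides")
constructed = build_pssm(instances)
frozen = load_lir_pssm()

print(f"consensus of the constructed profile: {constructed.consensus()}")
print(f"score range of the frozen profile: {frozen.min_score} .. {frozen.max_score}")
for pep in ("DDWDFL", "DDWTHL", "SGFTIV", "AVFQLV"):
    print(
        f"  {pep}: constructed {score_hexapeptide(constructed, pep):3d}   "
        f"frozen {score_hexapeptide(frozen, pep):3d}"
    )

pairs = reference_score_pairs()
exact = sum(1 for p, s in pairs.items() if score_hexapeptide(constructed, p) == s)
print(f"raw construction matches {exact}/{len(pairs)} reference scores exactly;")
print("the frozen profile (construction + reference calibration) matches all of")
print("them -- see docs/methods.md for the calibration procedure.")
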
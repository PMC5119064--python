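"""Regenerate the frozen LIR profile fixture (src/lirscan/data/lir_pssm.asc).

Builds the matrix from the 27 verified hexapeptides with the default
construction parameters, calibrates it against the full reference score set
(L1-minimal integer adjustment), verifies the result, and writes the ASCII
fixture.  Run from the repository root:

    python scripts/regenerate_pssm_fixture.py
"""

from pathlib import Path

from lirscan import (
    build_pssm,
    calibrate_to_reference,
    reference_score_pairs,
    score_hexapeptide,
    verified_hexapeptides,
    write_ascii_pssm,
)

def main() -> None:
    verified = verified_hexapeptides()
    assert len(verified) == 27, len(verified)
    pairs = reference_score_pairs()
    constructed = build_pssm(verified)
    raw_bad = sum(1 for p, s in pairs.items() if score_hexapeptide(constructed, p) != s)
    print(f"constructed matrix: {len(pairs) - raw_bad}/{len(pairs)} reference pairs exact")
    calibrated = calibrate_to_reference(constructed, pairs)
    bad = [(p, score_hexapeptide(calibrated, p), s) for p, s in pairs.items()
           if score_hexapeptide(calibrated, p) != s]
    assert not bad, bad
    change = int(abs(calibrated.scores - constructed.scores).sum())
    print(f"calibrated matrix reproduces all pairs; total |adjustment| = {change}")
    out = Path(__file__).resolve().parent.parent / "src" / "lirscan" / "data" / "lir_pssm.asc"
    write_ascii_pssm(calibrated, out)
    print(f"wrote {out}")

if __name__ == "__main__":
    main()
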
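import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lirscan import (
    PositionScoringMatrix,
    PssmConstructionParams,
    SequenceRecord,
    build_pssm,
    calibrate_evalues,
    calibrate_to_reference,
    load_background,
    read_ascii_pssm,
    scan_pssm,
    score_hexapeptide,
    write_ascii_pssm,
)
from lirscan.alphabet import AA_INDEX, STANDARD_AA
from lirscan.background import BackgroundFrequencies
from lirscan.datasets import reference_score_pairs, verified_hexapeptides
from lirscan.pssm import exact_null_distribution


@pytest.fixture(scope="module")
def constructed():
    return build_pssm(verified_hexapeptides())


class TestConstruction:
    def test_degenerate_alignment_peaks_at_observed_residues(self):
        m = build_pssm(["DDWDFL"] * 3)
        assert m.consensus() == "DDWDFL"

    def test_aromatic_column_sign_structure(self, constructed):
        # position 3 of the alignment holds only W/F/Y; everything else is
        # unobserved and must score negative
        row = constructed.scores[2]
        observed = {p[2] for p in verified_hexapeptides()}
        assert observed <= set("WFY")
        for aa in STANDARD_AA:
            if aa not in "WFY":
                assert row[AA_INDEX[aa]] < 0

    def test_unobserved_residues_score_negative_everywhere(self, constructed):
        peps = verified_hexapeptides()
        for j in range(6):
            observed = {p[j] for p in peps}
            for aa in set(STANDARD_AA) - observed - {"M"}:
                # M rides high on pseudocounts in the hydrophobic columns;
                # every other unobserved residue scores at most 0
                assert constructed.scores[j, AA_INDEX[aa]] <= 0

    def test_construction_reproduces_key_reference_scores(self, constructed):
        assert score_hexapeptide(constructed, "DDWDFL") == 26
        assert score_hexapeptide(constructed, "DDWTHL") == 24

    def test_construction_close_to_reference_set(self, constructed):
        """The raw construction tracks the reference scores closely; the
        calibrated fixture (see TestReferenceCalibration) matches exactly."""
        pairs = reference_score_pairs()
        diffs = [score_hexapeptide(constructed, p) - s for p, s in pairs.items()]
        assert max(abs(d) for d in diffs) <= 4
        assert np.mean(np.abs(diffs)) < 1.5

    def test_invalid_instances_rejected(self):
        with pytest.raises(ValueError):
            build_pssm(["DDWDF"])
        with pytest.raises(ValueError):
            build_pssm(["DDWDFX", "DDWDFL"])
        with pytest.raises(ValueError):
            build_pssm(["DDWDFL"])  # fewer than two instances


class TestScoring:
    def test_reference_examples(self, ref_pssm):
        assert score_hexapeptide(ref_pssm, "DDWTHL") == 24
        assert score_hexapeptide(ref_pssm, "AVFQLV") == 5

    def test_argmax_hexapeptide_attains_max_score(self, ref_pssm):
        best = ref_pssm.consensus()
        assert score_hexapeptide(ref_pssm, best) == ref_pssm.max_score
        assert score_hexapeptide(ref_pssm, "DDWTHL") <= ref_pssm.max_score

    def test_ambiguity_code_unscorable(self, ref_pssm):
        with pytest.raises(ValueError):
            score_hexapeptide(ref_pssm, "DDWTHX")


class TestScan:
    def test_window_count(self, ref_pssm):
        rec = SequenceRecord("a", "A" * 100)
        assert len(scan_pssm(rec, ref_pssm).windows) == 95

    def test_ambiguity_windows_omitted_and_flagged(self, ref_pssm):
        rec = SequenceRecord("a", "AAXAAAAAA")
        res = scan_pssm(rec, ref_pssm)
        assert res.skipped == (1, 2, 3)
        assert [w.start for w in res.windows] == [4]

    @settings(deadline=None, max_examples=40)
    @given(st.text(alphabet=STANDARD_AA, min_size=6, max_size=80))
    def test_window_scores_equal_direct_scoring(self, seq):
        from lirscan.datasets import load_lir_pssm

        pssm = load_lir_pssm()
        rec = SequenceRecord("a", seq)
        for w in scan_pssm(rec, pssm).windows:
            assert w.score == score_hexapeptide(pssm, w.peptide)
            assert w.peptide == seq[w.start - 1 : w.end]


class TestAsciiIO:
    def test_roundtrip(self, ref_pssm):
        sink = io.StringIO()
        write_ascii_pssm(ref_pssm, sink)
        back = read_ascii_pssm(io.StringIO(sink.getvalue()))
        assert np.array_equal(back.scores, ref_pssm.scores)

    def test_wrong_row_count_rejected(self, ref_pssm):
        sink = io.StringIO()
        write_ascii_pssm(ref_pssm, sink)
        lines = sink.getvalue().splitlines()
        extra = lines + [lines[-1].replace("  6 ", "  7 ", 1)]
        with pytest.raises(ValueError, match="rows"):
            read_ascii_pssm(io.StringIO("\n".join(extra)))

    def test_column_order_remapped(self):
        # same matrix written under a permuted alphabet must read back equal
        rng = np.random.default_rng(0)
        scores = rng.integers(-5, 10, size=(6, 20))
        m = PositionScoringMatrix(scores, STANDARD_AA, "external")
        perm = STANDARD_AA[::-1]
        text = ["      " + "  ".join(perm)]
        for j in range(6):
            row = " ".join(str(m.scores[j, AA_INDEX[a]]) for a in perm)
            text.append(f"{j + 1} X {row}")
        back = read_ascii_pssm(io.StringIO("\n".join(text)))
        assert np.array_equal(back.scores, m.scores)


class TestEvalues:
    def test_exact_null_matches_brute_force_on_small_alphabet(self, ref_pssm):
        # restrict the background to four residues and enumerate all 4^6
        letters = "DWLA"
        freq = {a: (0.25 if a in letters else 1e-9) for a in STANDARD_AA}
        bg4 = BackgroundFrequencies(freq)
        scores, tail = exact_null_distribution(ref_pssm, bg4)
        from itertools import product

        brute = {}
        for pep in product(letters, repeat=6):
            s = score_hexapeptide(ref_pssm, "".join(pep))
            brute[s] = brute.get(s, 0) + 1
        total = 4**6
        for s, count in brute.items():
            exact_tail = sum(c for t, c in brute.items() if t >= s) / total
            assert tail[np.searchsorted(scores, s)] == pytest.approx(
                exact_tail, rel=1e-6
            )

    def test_evalue_strictly_decreasing_in_score(self, ref_pssm, bg):
        cal = calibrate_evalues(ref_pssm, bg, search_space=100)
        evals = [cal.evalue(s) for s in range(ref_pssm.min_score, ref_pssm.max_score)]
        assert all(a >= b for a, b in zip(evals, evals[1:]))
        window = [cal.evalue(s) for s in range(0, 27)]
        assert all(a > b for a, b in zip(window, window[1:]))

    def test_evalue_at_minimum_score_equals_search_space(self, ref_pssm, bg):
        cal = calibrate_evalues(ref_pssm, bg, search_space=250)
        assert cal.evalue(ref_pssm.min_score) == pytest.approx(250.0)

    def test_tail_ratio_consistent_with_reference_evalues(self, ref_pssm, bg):
        # reference e-values print 8.4e-3 at score 20 and 2.2e-2 at 17;
        # the exact-null ratio agrees within a factor of two
        cal = calibrate_evalues(ref_pssm, bg, search_space=73)
        ratio = cal.evalue(20) / cal.evalue(17)
        printed = 8.4e-3 / 2.2e-2
        assert printed / 2 < ratio < printed * 2

    def test_degenerate_background_rejected(self, ref_pssm, bg):
        with pytest.raises(ValueError):
            calibrate_evalues(ref_pssm, bg, search_space=0.5)


class TestReferenceCalibration:
    def test_calibration_reproduces_all_reference_scores(self):
        constructed = build_pssm(verified_hexapeptides())
        pairs = reference_score_pairs()
        calibrated = calibrate_to_reference(constructed, pairs)
        mismatches = {
            p: (score_hexapeptide(calibrated, p), s)
            for p, s in pairs.items()
            if score_hexapeptide(calibrated, p) != s
        }
        assert mismatches == {}

    def test_infeasible_reference_set_raises(self, ref_pssm):
        with pytest.raises(RuntimeError):
            calibrate_to_reference(
                ref_pssm, {"DDWDFL": 26, "DDWDFI": 100}, bound=2
            )
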
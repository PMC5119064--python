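import itertools
import random

import pytest

from lirscan import (
    ConfusionMatrix,
    MotifFeatureVector,
    Scheme,
    cutoff_sweep,
    decide,
    evaluate,
    features_from_records,
)
from lirscan.predictor import round1


def fv(pep="DDWTHL", xlir=True, clir=False, anchor=False, score=None, verified=False):
    return MotifFeatureVector(pep, xlir, clir, anchor, score, verified)


class TestDecide:
    def test_conjunction_scheme_on_high_scoring_anchored_motif(self):
        f = fv(anchor=True, score=24)
        assert decide(Scheme.XLIR_A_AND_P, f, 13) is True

    def test_low_score_splits_and_from_or(self):
        f = fv(pep="SGFTIV", anchor=True, score=11)
        assert decide(Scheme.XLIR_A_AND_P, f, 13) is False
        assert decide(Scheme.XLIR_A_OR_P, f, 13) is True

    def test_strict_cutoff(self):
        f = fv(anchor=True, score=13)
        assert decide(Scheme.XLIR_A_AND_P, f, 13) is False
        assert decide(Scheme.XLIR_A_AND_P, f, 12) is True

    def test_non_xlir_negative_under_every_xlir_scheme(self):
        f = fv(xlir=False, clir=True, anchor=True, score=30)
        for scheme in (Scheme.XLIR, Scheme.XLIR_A, Scheme.XLIR_A_AND_P, Scheme.XLIR_A_OR_P):
            assert decide(scheme, f) is False

    def test_unscorable_peptide_fails_score_condition(self):
        f = fv(pep="DILVV", anchor=True, score=None)
        assert decide(Scheme.XLIR_A_AND_P, f, 13) is False
        assert decide(Scheme.XLIR_A_OR_P, f, 13) is True  # anchor satisfies the OR

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            decide("xlir+p|a", fv())


class TestEvaluate:
    def test_reference_clir_column(self):
        cm = ConfusionMatrix(TP=11, FP=2, TN=18, FN=16)
        m = cm.metrics().rounded()
        assert (m.accuracy, m.sensitivity, m.specificity, m.balanced_accuracy) == (
            61.7, 40.7, 90.0, 65.4)

    def test_reference_xlir_anchor_column(self):
        cm = ConfusionMatrix(TP=17, FP=4, TN=16, FN=10)
        m = cm.metrics().rounded()
        assert (m.accuracy, m.sensitivity, m.specificity, m.balanced_accuracy) == (
            70.2, 63.0, 80.0, 71.5)

    def test_perfect_predictor(self):
        labels = [True] * 27 + [False] * 20
        cm, m = evaluate(labels, labels)
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (27, 20, 0, 0)
        assert m.accuracy == 100.0

    def test_undefined_metrics_reported_as_none(self):
        cm, m = evaluate([True, True], [True, True])
        assert m.specificity is None and m.balanced_accuracy is None
        assert m.sensitivity == 100.0
        cm, m = evaluate([False], [False])
        assert m.sensitivity is None

    def test_balanced_accuracy_identity(self):
        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(1, 40)
            preds = [rng.random() < 0.5 for _ in range(n)]
            labels = [rng.random() < 0.5 for _ in range(n)]
            _, m = evaluate(preds, labels)
            if m.sensitivity is not None and m.specificity is not None:
                assert m.balanced_accuracy == (m.sensitivity + m.specificity) / 2

    def test_metrics_invariant_under_permutation(self):
        preds = [True, False, True, True, False]
        labels = [True, True, False, True, False]
        _, base = evaluate(preds, labels)
        order = [3, 1, 4, 0, 2]
        _, perm = evaluate([preds[i] for i in order], [labels[i] for i in order])
        assert perm == base


class TestCutoffSweep:
    def test_counts_non_increasing(self, records):
        feats = [f for f in features_from_records(records) if f.scorable]
        rows = cutoff_sweep(feats, range(0, 30))
        for a, b in zip(rows, rows[1:]):
            assert a.verified_above >= b.verified_above
            assert a.unverified_above >= b.unverified_above

    def test_vacuous_cutoff(self, records):
        feats = [f for f in features_from_records(records) if f.scorable]
        row = cutoff_sweep(feats, [min(f.pssm_score for f in feats) - 1])[0]
        assert row.verified_above + row.unverified_above == 47
        m = row.metrics.rounded()
        assert m.sensitivity == 100.0 and m.specificity == 0.0

    def test_unscorable_feature_rejected(self):
        with pytest.raises(ValueError):
            cutoff_sweep([fv(pep="DILVV", score=None)], [13])


def test_round1_half_up():
    assert round1(65.35) == 65.4
    assert round1(50.648) == 50.6
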
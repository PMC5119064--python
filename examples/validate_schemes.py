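"""Reproduce the validation arithmetic of the LIR prediction schemes.

Evaluates the six decision schemes over the 47 xLIR-matching candidates of
the design set (27 verified, 20 unverified) and sweeps the profile-score
cutoff.  Prints confusion counts and percentages; sensitivity counts how
many verified LIRs a scheme recovers, specificity how many unverified
candidates it rejects.
"""

from lirscan import cutoff_sweep, decide, evaluate, features_from_records
from lirscan.predictor import Scheme

features = features_from_records(block="alemu")
labels = [f.verified for f in features]
print(f"{len(features)} candidate motifs: {sum(labels)} verified, "
      f"{len(labels) - sum(labels)} unverified\n")

print("scheme        TP  FP  TN  FN    ACC   Sens   Spec   BACC")
for scheme in Scheme:
    cm, metrics = evaluate([decide(scheme, f, cutoff=13) for f in features], labels)
    m = metrics.rounded()
    print(
        f"{scheme.value:<12} {cm.TP:3d} {cm.FP:3d} {cm.TN:3d} {cm.FN:3d} "
        f"{m.accuracy:6.1f} {m.sensitivity:6.1f} {m.specificity:6.1f} "
        f"{m.balanced_accuracy:6.1f}"
    )

print("\ncutoff sweep (strict score > c, xLIR-matching candidates):")
print("c   verified>c unverified>c   Sens   Spec   BACC")
for row in cutoff_sweep([f for f in features if f.scorable], range(9, 19)):
    m = row.metrics.rounded()
    print(
        f"{row.cutoff:<3d} {row.verified_above:9d} {row.unverified_above:12d} "
        f"{m.sensitivity:6.1f} {m.specificity:6.1f} {m.balanced_accuracy:6.1f}"
    )
print("\nA cutoff of 16 gives the best balanced accuracy (83.9): it keeps 21")
print("of 27 verified LIRs while rejecting 18 of 20 unverified candidates.")
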
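"""Two-phase verification: triage, review, extrapolated test characteristics.

Predicted positives (probability >= 0.90) are all reviewed; predicted
negatives are sampled (all ED notes, 10% of outpatient notes) and the
negative arm is scaled by 1/f to estimate the false negatives nobody read.
This example runs the packaged review counts from a published e-scooter
surveillance study through the diagnostics module.
"""
import scootersurv as ss
from scootersurv.studydata import reference_confusion

est = reference_confusion()
for name in ("ED", "outpatient"):
    cm = est.stratum(name)
    chars = ss.test_characteristics(cm)
    print(f"{name}: TP={cm.tp:.0f} FP={cm.fp:.0f} "
          f"FN*={cm.fn:.0f} TN*={cm.tn:.0f} (f={cm.sampling_fraction})")
    print(f"  PPV {100 * chars.ppv:.0f}%  sensitivity {100 * chars.sensitivity:.0f}%  "
          f"specificity {100 * chars.specificity:.0f}%")

combined = ss.test_characteristics(est.combined)
print("\ncombined:", combined.rounded())
print("(* = extrapolated; accuracy and LR+ describe how well the classifier")
print(" separates injuries from confusers among keyword-matching notes)")

prevalence = ss.adjusted_prevalence(est.stratum("outpatient"), mode="observed")
workload = ss.workload_estimate(est.stratum("outpatient").tp, prevalence)
print(f"\nadjusted outpatient prevalence: {100 * prevalence:.1f}%")
print(f"notes a keyword-only screen would need reviewed: {workload}")
print(f"extrapolated injuries missed below threshold: "
      f"{est.stratum('outpatient').fn:.0f}")
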
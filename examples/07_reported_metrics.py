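"""Recompute the published performance metrics from the published
variant-level calls.

The original study reported per-variant truth/prediction tables for both
drugs; feeding those label pairs through the evaluation module
reproduces the reported metric table exactly.
"""

import angleforest as af

for drug in ("dabrafenib", "vemurafenib"):
    calls = af.known_calls(drug)
    cm, rep = af.confusion_and_metrics(calls["status"], calls["prediction"])
    print(f"\n{drug} ({len(calls)} variants with known status)")
    print(f"  confusion (R positive): TP={cm.tp} FP={cm.fp} "
          f"TN={cm.tn} FN={cm.fn}")
    print(f"  accuracy    {100 * rep.accuracy:6.2f}%")
    print(f"  specificity {rep.specificity:6.2f}")
    print(f"  MCC         {rep.mcc:6.2f}")
    print(f"  sensitive  P/R/F1: {rep.sensitive.precision:.2f} "
          f"{rep.sensitive.recall:.2f} {rep.sensitive.f1:.2f}")
    print(f"  resistant  P/R/F1: {rep.resistant.precision:.2f} "
          f"{rep.resistant.recall:.2f} {rep.resistant.f1:.2f}")

print("\nreported calls for the variants of uncertain significance:")
print(af.vus_calls("dabrafenib").to_string(index=False))
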
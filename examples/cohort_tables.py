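"""Cohort aggregation over the bundled reference study tables.

The package ships the per-subject summary accuracies of a 12-participant
frustration-BCI study.  This script recomputes every cohort mean from the
raw per-subject values, plus the precision/recall of the averaged
frustration-decoder confusion matrix.
"""

from frustmi import aggregate_cohort, confusion_metrics
from frustmi.datasets import (
    reference_method_accuracy,
    reference_mi_accuracy,
    reference_pbci_accuracy,
    reference_state_confusion,
)

mean, std = aggregate_cohort(reference_pbci_accuracy())
print(f"frustration decoder (3-class): {mean:.1f}% mean accuracy")

print("\nMI accuracy by training condition:")
mi = reference_mi_accuracy()
for cond in ("low", "mid", "high", "all"):
    mean, _ = aggregate_cohort(mi[cond])
    print(f"  {cond:>4}: {mean:.2f}%")

print("\nMI accuracy by decision strategy:")
methods = reference_method_accuracy()
means = {}
for m in ("1", "2", "3-1", "3-2"):
    means[m], _ = aggregate_cohort(methods[m])
    print(f"  method {m:>3}: {means[m]:.2f}%")
print(f"  fusion improvement over pooled baseline: "
      f"{means['2'] - means['3-1']:.2f} points")

print("\nfrustration decoder confusion metrics (equal priors):")
print(confusion_metrics(reference_state_confusion(),
                        classes=["low", "mid", "high"]).round(1))
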
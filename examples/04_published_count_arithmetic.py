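"""Reproduce published sensitivity/specificity from printed counts.

The original farm study prints, per behaviour category, how many test
windows the final models predicted as biting / no-biting.  Feeding those
counts through the package's evaluation code must reproduce the printed
percentages — a pure-arithmetic cross-check of the confusion metrics.
"""

from pentail import reference
from pentail.evaluation import category_breakdown, confusion_at, metrics

for model in ("lstm", "cnn"):
    counts = reference.CATEGORY_COUNTS[model]["combined"]
    probs, labels, cats = reference.synthesize_scores(counts)
    m = metrics(confusion_at(probs, labels, 0.5))
    print(f"{model.upper():4s} combined: sensitivity {100 * m.sensitivity:6.2f}%  "
          f"specificity {100 * m.specificity:6.2f}%")
    table = category_breakdown(probs, labels, cats, 0.5)
    print(table.to_string(index=False))
    print()
# The LSTM detects ~89% of biting windows but flags many non-biting
# windows (specificity ~53%); the CNN is the mirror image (37% / 92%).
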
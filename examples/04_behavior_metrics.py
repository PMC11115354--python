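"""Behavioral outcome measures on a hand-built set of predictions.

Shows the entropy/confidence metrics and the confusion-table machinery on a
transparent fixture: a perfectly confident hit, a coin-flip between two
neighbors, and a maximally uncertain (uniform) response, followed by a
ranked misclassification table and the regular-minus-delay differential.
"""

import numpy as np

from cochmat.behavior import (
    accuracy_differential,
    confusion,
    summarize_test,
    top_misclassifications,
)
from cochmat.training import PredictiveDistribution

labels = ["tree", "three", "go", "no"]


def pd_(probs):
    probs = np.asarray(probs, float)
    return PredictiveDistribution(probs, tuple(labels), labels[int(np.argmax(probs))])


results = [pd_([1, 0, 0, 0]), pd_([0.5, 0.5, 0, 0]), pd_([0.25] * 4), pd_([0, 0, 0.9, 0.1])]
true = ["tree", "three", "go", "go"]
trials, agg = summarize_test(results, true)
print("per-trial records:")
print(trials.to_string(index=False))
print("\naggregates (entropy in bits; log2(4) = 2 is maximal here):")
for k, v in agg.items():
    print(f"  {k}: {v:.4f}" if isinstance(v, float) else f"  {k}: {v}")

table = confusion(true, [r.predicted_word for r in results], labels)
print("\nranked misclassification cells:")
for row in top_misclassifications(table, k=5):
    print(f"  {row.word} -> {row.misclassified_as}: {row.count}/{row.total_misclassifications}"
          f" = {row.proportion_percent}%")

diff = accuracy_differential({"tree": 80.0, "go": 70.0}, {"tree": 55.4, "go": 81.11})
print("\nregular-minus-delay accuracy differential (positive = regular advantage):")
print(" ", diff)
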
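"""The evaluation-metric suite on a reconstructed confusion matrix.

Counts below correspond to an external test set of 30 blockers and 14
non-blockers scored at the 0.5 probability threshold.
"""

from hergstack import (
    ConfusionCounts,
    auc_roc,
    compute_classification_metrics,
    percent_improvement,
)

counts = ConfusionCounts(tp=25, tn=11, fp=3, fn=5)
report = compute_classification_metrics(counts)
print("confusion counts:", counts)
print("metrics:", report.formatted())
# SEN/SPE are the per-class recalls, PPV/NPV the per-prediction precisions,
# MCC a balanced single-number summary in [-1, 1], B-ACC = (SEN+SPE)/2.

auc = auc_roc([1, 1, 0, 0, 1], [0.9, 0.4, 0.3, 0.6, 0.7])
print(f"AUC of a small scored set: {auc:.3f}")

gain = percent_improvement(0.860, 0.840)
print(f"improvement of 0.860 over a 0.840 baseline: {gain:+.2f}%")
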
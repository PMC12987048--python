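"""Confusion-derived metrics, Wilson intervals, and majority voting.

Recomputes a window-level metric report from raw confusion counts and
demonstrates the subject-level decision rule: per-window argmax votes,
modal class, and mean voted-class probability as the confidence.
"""

import numpy as np

from frontaleeg.evaluation import (
    ConfusionCounts,
    confusion_metrics,
    majority_vote,
    wilson_ci,
)

# a window-level test set: 194 HC windows (186 correct), 232 MDD (212 correct)
report = confusion_metrics(ConfusionCounts(tp=212, tn=186, fp=8, fn=20),
                           descriptive_windows=True)
print(report.to_table())
print(f"\nbalanced accuracy {report.balanced_accuracy:.4f}  MCC {report.mcc:.4f}")
lo, hi = report.wilson_ci
print(f"accuracy {100 * report.accuracy:.2f}% (Wilson 95% CI"
      f" {100 * lo:.2f}-{100 * hi:.2f}%)")

lo, hi = wilson_ci(12, 12)
print(f"\n12/12 correct subjects: Wilson 95% CI {100 * lo:.1f}-{100 * hi:.1f}%")

# subject decision from 11 window probabilities: 7 MDD votes vs 4 HC votes
probs = np.vstack([np.tile([0.25, 0.75], (7, 1)), np.tile([0.85, 0.15], (4, 1))])
pred = majority_vote(probs, subject_id="S013")
print(f"\nsubject {pred.subject_id}: voted {pred.voted_label} "
      f"({pred.votes_mdd} MDD vs {pred.votes_hc} HC), "
      f"confidence {pred.confidence:.2f}")
# confidence is the mean probability the model assigned to the voted class
# across all 11 windows, not just the winning ones.
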
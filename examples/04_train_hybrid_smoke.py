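"""Train the hybrid fusion model end to end at smoke scale (~4 min CPU).

A small well-separated synthetic cohort is split subject-independently,
the hybrid model (selected configuration) is trained briefly with
augmentation and class weighting, and held-out subjects are scored by
majority voting.
"""

import numpy as np
import pandas as pd

from frontaleeg.augmentation import AugmentConfig
from frontaleeg.evaluation import majority_vote, subject_level_report
from frontaleeg.features import compute_bundles
from frontaleeg.models import HybridConfig, build_hybrid
from frontaleeg.preprocessing import prepare_windows
from frontaleeg.synthetic import simulate_cohort, well_separated_spec
from frontaleeg.training import group_split, split_bundles, train

recordings, _ = simulate_cohort(well_separated_spec(10, 10, seed=1, duration_s=90.0))
ws, _, _ = prepare_windows(recordings, L=3840, p=50)
bundles = compute_bundles(ws)
split = group_split(list(bundles.subject_ids), list(bundles.labels),
                    test_fraction=0.25, val_fraction=0.2, seed=1)
parts = split_bundles(bundles, split)
print({k: f"{len(set(v.subject_ids))} subjects / {v.n} windows"
       for k, v in parts.items()})

spec, model = build_hybrid(HybridConfig(), L=3840, seed=1)
print(f"hybrid model: {spec.total_params:,} parameters")
model, history = train(model, parts, augment_cfg=AugmentConfig(), epochs=12,
                       batch_size=32, seed=1, early_stop_patience=5,
                       plateau_patience=3, verbose=True)

test = parts["test"]
preds, truth = [], {}
for sid in pd.unique(test.subject_ids):
    mask = test.subject_ids == sid
    probs = model.predict_proba(test.raw[mask], test.maps[mask], test.glob[mask])
    preds.append(majority_vote(probs, subject_id=str(sid)))
    truth[str(sid)] = str(test.labels[mask][0])
report = subject_level_report(preds, truth)
print(f"\nheld-out subject-level accuracy: {report.accuracy:.2f} "
      f"(sensitivity {report.extras['sensitivity']:.2f}, "
      f"specificity {report.extras['specificity']:.2f})")
# With the strong programmed contrast most held-out subjects vote correctly
# even at this tiny training budget; real cohorts need the full two-stage
# hyperparameter search and longer refinement.
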
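"""Reference classical baseline over the 17-dim global feature vector.

A single logistic-regression pipeline for sanity-checking the feature
protocol: features are standardized with a scaler fitted on the training
subjects only, the classifier is trained at the window level with
inverse-frequency class weighting, and subject decisions use the same
majority-vote rule as the deep models.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .evaluation import majority_vote
from .features import FeatureBundleSet
from .io_formats import SubjectPrediction
from .training import LABEL_INDEX


def fit_logistic_baseline(train: FeatureBundleSet, seed: int = 42):
    """Window-level logistic regression on standardized global vectors."""
    y = np.array([LABEL_INDEX[lab] for lab in train.labels])
    clf = make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, class_weight="balanced", random_state=seed),
    )
    clf.fit(train.glob, y)
    return clf


def predict_subjects(clf, bundle: FeatureBundleSet) -> list[SubjectPrediction]:
    """Score a bundle and aggregate windows per subject by majority vote."""
    import pandas as pd

    probs = clf.predict_proba(bundle.glob)
    preds = []
    for sid in pd.unique(bundle.subject_ids):
        mask = bundle.subject_ids == sid
        preds.append(majority_vote(probs[mask], subject_id=str(sid)))
    return preds
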
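"""Window- and subject-level evaluation.

Metrics are derived from a 2x2 confusion table with MDD as the positive
class: accuracy, per-class precision/recall/F1, macro and support-weighted
averages, balanced accuracy, the Matthews correlation coefficient, and
Wilson score intervals on proportions.  Subject-level decisions aggregate
window-level softmax outputs by majority voting; the reported confidence is
the mean probability assigned to the voted class across a recording's
windows.

Window-level metrics are flagged descriptive throughout: overlapped windows
from one recording share samples and are not independent trials, so the
subject/recording is the unit of independent evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import HC, MDD, SubjectPrediction

CLASSES = (HC, MDD)  # index 0 = HC, index 1 = MDD (positive class)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table; MDD is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    mcc: float
    wilson_ci: tuple[float, float]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    descriptive_windows: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_table(self) -> str:
        """Human-readable per-class table (precision / recall / F1 / support)."""
        lines = [f"{'':>12} {'precision':>9} {'recall':>7} {'f1':>6} {'support':>8}"]
        for c in CLASSES:
            lines.append(
                f"{c:>12} {self.precision[c]:>9.2f} {self.recall[c]:>7.2f} "
                f"{self.f1[c]:>6.2f} {self.support[c]:>8d}"
            )
        n = sum(self.support.values())
        lines.append(f"{'accuracy':>12} {'':>9} {'':>7} {self.accuracy:>6.2f} {n:>8d}")
        lines.append(
            f"{'macro avg':>12} {self.macro_avg['precision']:>9.2f} "
            f"{self.macro_avg['recall']:>7.2f} {self.macro_avg['f1']:>6.2f} {n:>8d}"
        )
        lines.append(
            f"{'weighted avg':>12} {self.weighted_avg['precision']:>9.2f} "
            f"{self.weighted_avg['recall']:>7.2f} {self.weighted_avg['f1']:>6.2f} {n:>8d}"
        )
        return "\n".join(lines)


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n.

    Better small-n coverage than the Wald interval; bounds are clipped
    to [0, 1] and always bracket k/n.
    """
    if n < 1:
        raise ValueError("wilson_ci requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    z = norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = p + z * z / (2.0 * n)
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    # clip to [0, 1] and guard the p-hat bracketing against rounding
    lo = min(max(0.0, (center - half) / denom), p)
    hi = max(min(1.0, (center + half) / denom), p)
    return (lo, hi)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion_metrics(c: ConfusionCounts, *, descriptive_windows: bool = False) -> MetricsReport:
    """Full metric report from a confusion table.

    MCC follows the standard 2x2 definition
    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero marginal
    makes the denominator zero and the metric is defined as 0.
    """
    n = c.total
    acc = (c.tp + c.tn) / n
    # per-class views: HC treats TN as its "true positives"
    prec = {HC: _safe_div(c.tn, c.tn + c.fn), MDD: _safe_div(c.tp, c.tp + c.fp)}
    rec = {HC: _safe_div(c.tn, c.tn + c.fp), MDD: _safe_div(c.tp, c.tp + c.fn)}
    f1 = {
        cls: _safe_div(2 * prec[cls] * rec[cls], prec[cls] + rec[cls]) for cls in CLASSES
    }
    support = {HC: c.tn + c.fp, MDD: c.tp + c.fn}
    bal_acc = 0.5 * (rec[HC] + rec[MDD])

    denom = (
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (float(c.tp) * c.tn - float(c.fp) * c.fn) / np.sqrt(denom)

    macro = {
        "precision": np.mean([prec[cls] for cls in CLASSES]),
        "recall": np.mean([rec[cls] for cls in CLASSES]),
        "f1": np.mean([f1[cls] for cls in CLASSES]),
    }
    weighted = {
        key: sum(vals[cls] * support[cls] for cls in CLASSES) / n
        for key, vals in (("precision", prec), ("recall", rec), ("f1", f1))
    }
    return MetricsReport(
        accuracy=acc,
        balanced_accuracy=bal_acc,
        mcc=float(mcc),
        wilson_ci=wilson_ci(c.tp + c.tn, n),
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        macro_avg={k: float(v) for k, v in macro.items()},
        weighted_avg={k: float(v) for k, v in weighted.items()},
        descriptive_windows=descriptive_windows,
    )


def majority_vote(
    window_probs: np.ndarray, subject_id: str = "", true_label: str | None = None
) -> SubjectPrediction:
    """Aggregate K window softmax outputs into one subject decision.

    Votes are per-window argmax over (p_HC, p_MDD); the subject label is the
    modal class.  An exact tie resolves by argmax over the vote-count vector,
    i.e. the first class index (HC).  Confidence is the mean probability of
    the voted class over all K windows.
    """
    probs = np.asarray(window_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2 or probs.shape[0] < 1:
        raise ValueError("window_probs must be a nonempty K x 2 array")
    votes = np.argmax(probs, axis=1)
    counts = np.bincount(votes, minlength=2)
    winner = int(np.argmax(counts))  # ties -> index 0 (HC)
    conf = float(np.mean(probs[:, winner]))
    return SubjectPrediction(
        subject_id=subject_id,
        voted_label=CLASSES[winner],
        n_windows=int(probs.shape[0]),
        votes_hc=int(counts[0]),
        votes_mdd=int(counts[1]),
        confidence=conf,
        true_label=true_label,
    )


def subject_level_report(
    preds: Sequence[SubjectPrediction], true_labels: Mapping[str, str]
) -> MetricsReport:
    """Subject-level confusion metrics with sensitivity/specificity CIs.

    Sensitivity is MDD recall, specificity is HC recall; each carries its
    own Wilson interval computed over that class's subjects.
    """
    if not preds:
        raise ValueError("no subject predictions supplied")
    tp = tn = fp = fn = 0
    for p in preds:
        if p.subject_id not in true_labels:
            raise KeyError(f"no true label for subject {p.subject_id!r}")
        truth, guess = true_labels[p.subject_id], p.voted_label
        if truth == MDD:
            tp, fn = (tp + 1, fn) if guess == MDD else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if guess == HC else (tn, fp + 1)
    report = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    report.extras["sensitivity"] = report.recall[MDD]
    report.extras["specificity"] = report.recall[HC]
    report.extras["sensitivity_ci"] = wilson_ci(tp, tp + fn) if tp + fn else None
    report.extras["specificity_ci"] = wilson_ci(tn, tn + fp) if tn + fp else None
    return report


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta effect size, computed exactly over all pairs.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y), in [-1, 1].
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = xa[:, None] - ya[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (xa.size * ya.size))


def bootstrap_mean_ci(
    values: Sequence[float], B: int = 4000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean with B resamples."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(B, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))
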
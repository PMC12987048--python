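"""Subject-independent training protocol.

Splitting is group-aware at the participant level (GroupShuffleSplit):
~80% of subjects form a development set and ~20% a held-out test set; a
second subject-level split carves ~85%/~15% training/validation subsets out
of the development set.  Every window inherits its subject's partition, so
the three window-level partitions are disjoint by construction; a leakage
audit asserts this on every produced split.

Training minimizes class-weighted soft-label cross-entropy with Adam,
augmenting only the training stream (noise/drift/scale per window, MixUp
per batch).  Validation accuracy drives both callbacks: ReduceLROnPlateau
(factor 0.5 after a patience plateau) and early stopping with best-weight
restoration.  Hyperparameters are chosen by a two-stage procedure: a
short-run randomized search over the candidate grid, then longer
refinement of the top-k configurations, selecting by refinement-stage (not
short-run) validation accuracy; the winner is refit once on the combined
training and validation subjects before the single test evaluation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit

from .augmentation import (
    AugmentConfig,
    SEAugmentConfig,
    augment_window,
    mixup_batch,
    se_augment_window,
)
from .features import FeatureBundleSet
from .io_formats import HC, MDD
from .models import HybridConfig, HybridModel, build_hybrid, make_optimizer
from .nnet import Adam, weighted_softmax_xent

LABEL_INDEX = {HC: 0, MDD: 1}


class LeakageError(RuntimeError):
    """A subject appeared in more than one partition."""


@dataclass(frozen=True)
class SubjectSplit:
    train_subjects: frozenset
    val_subjects: frozenset
    test_subjects: frozenset
    seed: int

    @property
    def dev_subjects(self) -> frozenset:
        return self.train_subjects | self.val_subjects

    def partition_of(self, subject_id: str) -> str:
        for name in ("train", "val", "test"):
            if subject_id in getattr(self, f"{name}_subjects"):
                return name
        raise KeyError(subject_id)

    def audit(self, subject_ids: Sequence[str] | None = None) -> None:
        """Hard leakage check: the three subject sets are pairwise disjoint."""
        sets = (self.train_subjects, self.val_subjects, self.test_subjects)
        for a, b in itertools.combinations(sets, 2):
            if a & b:
                raise LeakageError(f"subjects in two partitions: {sorted(a & b)}")
        if subject_ids is not None:
            missing = set(subject_ids) - (self.dev_subjects | self.test_subjects)
            if missing:
                raise LeakageError(f"subjects outside any partition: {sorted(missing)}")


def group_split(
    subject_ids: Sequence[str],
    labels: Sequence[str],
    test_fraction: float = 0.20,
    val_fraction: float = 0.15,
    seed: int = 42,
) -> SubjectSplit:
    """Two-stage subject-level random partition (dev/test, then train/val).

    Deterministic given the seed.  With very small cohorts a partition can
    end up without one class; that is reported as a warning, not an error.
    """
    import warnings

    subjects = pd.unique(np.asarray(subject_ids, dtype=object))
    subj_label = dict(zip(subject_ids, labels))
    y = np.array([subj_label[s] for s in subjects], dtype=object)
    gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    dev_idx, test_idx = next(gss.split(subjects, y, groups=subjects))
    dev = subjects[dev_idx]
    gss2 = GroupShuffleSplit(n_splits=1, test_size=val_fraction, random_state=seed)
    train_idx, val_idx = next(gss2.split(dev, y[dev_idx], groups=dev))
    split = SubjectSplit(
        train_subjects=frozenset(dev[train_idx]),
        val_subjects=frozenset(dev[val_idx]),
        test_subjects=frozenset(subjects[test_idx]),
        seed=seed,
    )
    split.audit(subjects)
    for name in ("train", "val", "test"):
        part = getattr(split, f"{name}_subjects")
        present = {subj_label[s] for s in part}
        if part and present != {HC, MDD}:
            warnings.warn(
                f"{name} partition lacks class(es) {sorted({HC, MDD} - present)}",
                RuntimeWarning,
                stacklevel=2,
            )
    return split


def class_weights(train_labels: Sequence[str]) -> np.ndarray:
    """Inverse-frequency, mean-normalized: w_c = N_total / (2 * N_c)."""
    labels = np.asarray(train_labels, dtype=object)
    counts = np.array([np.sum(labels == HC), np.sum(labels == MDD)], dtype=float)
    if np.any(counts == 0):
        raise ValueError("both classes must be present in the training labels")
    return counts.sum() / (2.0 * counts)


def one_hot(labels: Sequence[str]) -> np.ndarray:
    y = np.zeros((len(labels), 2), dtype=np.float64)
    for i, lab in enumerate(labels):
        y[i, LABEL_INDEX[lab]] = 1.0
    return y


def split_bundles(
    bundles: FeatureBundleSet, split: SubjectSplit
) -> dict[str, FeatureBundleSet]:
    """Window-level partitions induced purely by subject membership."""
    split.audit()
    out = {}
    for name in ("train", "val", "test"):
        members = getattr(split, f"{name}_subjects")
        mask = np.array([s in members for s in bundles.subject_ids])
        out[name] = bundles.subset(mask)
    return out


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def _evaluate(model, bundle: FeatureBundleSet,
              weights: np.ndarray) -> tuple[float, float]:
    if isinstance(model, HybridModel):
        probs = model.predict_proba(bundle.raw, bundle.maps, bundle.glob)
    else:
        probs = model.predict_proba(bundle.raw)
    y = one_hot(bundle.labels)
    eps = 1e-12
    w = y @ weights
    loss = float(np.mean(w * -(y * np.log(probs + eps)).sum(axis=1)))
    acc = float(np.mean(np.argmax(probs, axis=1) == np.argmax(y, axis=1)))
    return loss, acc


def train(
    model: HybridModel,
    bundles: dict[str, FeatureBundleSet],
    augment_cfg: AugmentConfig | None = None,
    epochs: int = 150,
    batch_size: int = 64,
    seed: int = 42,
    early_stop_patience: int = 15,
    plateau_patience: int = 5,
    lr_factor: float = 0.5,
    min_lr: float = 1e-5,
    optimizer: Adam | None = None,
    verbose: bool = False,
) -> tuple[HybridModel, TrainingHistory]:
    """Train on bundles['train'], monitoring bundles['val'].

    Augmentation and MixUp touch only the training stream; validation is
    always evaluated on unaugmented windows.  Early stopping restores the
    best-validation-accuracy weights.  With epochs=0 the initial weights
    are returned and the history is empty.
    """
    train_b, val_b = bundles["train"], bundles["val"]
    if train_b.n == 0:
        raise ValueError("empty training stream")
    cw = class_weights(train_b.labels)
    rng = np.random.default_rng(seed)
    opt = optimizer or make_optimizer(model)
    hist = TrainingHistory()
    cfg = augment_cfg
    hybrid = isinstance(model, HybridModel)
    y_train = one_hot(train_b.labels)
    best_weights = model.get_weights()
    best_val, best_epoch, since_best, since_plateau = -np.inf, -1, 0, 0

    for epoch in range(epochs):
        order = rng.permutation(train_b.n)
        losses, hits, seen = [], 0, 0
        for i in range(0, train_b.n, batch_size):
            idx = order[i : i + batch_size]
            raw = train_b.raw[idx]
            if isinstance(cfg, SEAugmentConfig):
                raw = np.stack([se_augment_window(w, cfg, rng) for w in raw])
            elif cfg is not None:
                raw = np.stack([augment_window(w, cfg, rng) for w in raw])
            if hybrid:
                inputs = HybridModel.prepare_inputs(
                    raw, train_b.maps[idx], train_b.glob[idx]
                )
            else:
                inputs = (raw.astype(np.float32),)
            y = y_train[idx]
            if (isinstance(cfg, AugmentConfig) and cfg.mixup_enabled
                    and y.shape[0] >= 2):
                inputs, y = mixup_batch(inputs, y, cfg.mixup_alpha, rng)
            logits = model.forward(inputs, training=True, rng=rng)
            loss, grad = weighted_softmax_xent(logits, y, cw)
            model.backward(grad)
            opt.step(model.all_layers())
            losses.append(loss)
            hits += int(np.sum(np.argmax(logits, axis=1) == np.argmax(y, axis=1)))
            seen += y.shape[0]
        val_loss, val_acc = _evaluate(model, val_b, cw)
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_acc.append(hits / seen)
        hist.val_loss.append(val_loss)
        hist.val_acc.append(val_acc)
        hist.lr.append(opt.lr)
        if verbose:
            print(
                f"epoch {epoch+1:3d}  loss {hist.train_loss[-1]:.4f}  "
                f"acc {hist.train_acc[-1]:.3f}  val_acc {val_acc:.3f}  lr {opt.lr:.2e}"
            )
        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch
            best_weights = model.get_weights()
            since_best = since_plateau = 0
        else:
            since_best += 1
            since_plateau += 1
            if since_plateau >= plateau_patience and opt.lr > min_lr:
                opt.lr = max(opt.lr * lr_factor, min_lr)
                since_plateau = 0
            if since_best >= early_stop_patience:
                break
    if hist.val_acc:
        model.set_weights(best_weights)
        hist.best_epoch = best_epoch
        hist.best_val_acc = best_val
    return model, hist


@dataclass(frozen=True)
class SearchSpace:
    """Candidate sets for the randomized hyperparameter search."""

    emb_raw: tuple = (128, 192, 256)
    head_units: tuple = (128, 256, 384)
    lr_init: tuple = (5e-4, 8e-4, 1e-3)
    map_drop: tuple = (0.25, 0.30, 0.35)
    map_filters: tuple = ((32, 64), (48, 96))
    raw_drop: tuple = ((0.25, 0.35, 0.45), (0.3, 0.4, 0.5))
    raw_filters: tuple = ((64, 128, 256), (96, 192, 256))
    wd: tuple = (5e-5, 1e-4)

    def fields(self) -> dict[str, tuple]:
        return asdict(self)

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.fields().values()]))

    def contains(self, cfg: HybridConfig) -> bool:
        d = cfg.to_dict()
        return all(d[k] in v for k, v in self.fields().items())

    def sample(self, n: int, seed: int) -> list[HybridConfig]:
        """n distinct configurations, uniform over the grid, without replacement."""
        rng = np.random.default_rng(seed)
        n = min(n, self.size)
        seen: set[tuple] = set()
        out: list[HybridConfig] = []
        fields = self.fields()
        while len(out) < n:
            choice = tuple(
                values[rng.integers(len(values))] for values in fields.values()
            )
            if choice in seen:
                continue
            seen.add(choice)
            out.append(HybridConfig(**dict(zip(fields.keys(), choice))))
        return out


TRIAL_COLUMNS = (
    "trial", "val_acc", "emb_raw", "head_units", "lr_init", "map_drop",
    "map_filters", "raw_drop", "raw_filters", "wd",
)


def _trial_row(trial: int, val_acc: float, cfg: HybridConfig) -> dict:
    d = cfg.to_dict()
    return {"trial": trial, "val_acc": val_acc, **{k: d[k] for k in TRIAL_COLUMNS[2:]}}


def random_search(
    bundles: dict[str, FeatureBundleSet],
    space: SearchSpace | None = None,
    n_trials: int = 12,
    seed: int = 42,
    epochs: int = 40,
    L: int | None = None,
    train_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Stage 1: short-run randomized search, ranked by best validation accuracy.

    The split is fixed before the search and test windows are never
    touched; each trial trains the hybrid model briefly with early stopping.
    """
    space = space or SearchSpace()
    L = L or bundles["train"].raw.shape[1]
    configs = space.sample(n_trials, seed)
    rows = []
    kwargs = dict(train_kwargs or {})
    kwargs.setdefault("epochs", epochs)
    for t, cfg in enumerate(configs, start=1):
        _, model = build_hybrid(cfg, L=L, seed=seed + t)
        _, hist = train(model, bundles, augment_cfg=AugmentConfig(), seed=seed + t,
                        **kwargs)
        rows.append(_trial_row(t, float(np.max(hist.val_acc)), cfg))
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return table.sort_values("val_acc", ascending=False).reset_index(drop=True)


def _cfg_from_row(row: pd.Series) -> HybridConfig:
    return HybridConfig(
        emb_raw=int(row["emb_raw"]),
        head_units=int(row["head_units"]),
        lr_init=float(row["lr_init"]),
        map_drop=float(row["map_drop"]),
        map_filters=tuple(row["map_filters"]),
        raw_drop=tuple(row["raw_drop"]),
        raw_filters=tuple(row["raw_filters"]),
        wd=float(row["wd"]),
    )


def refine_top_k(
    trials: pd.DataFrame,
    bundles: dict[str, FeatureBundleSet],
    k: int = 3,
    long_epochs: int = 150,
    final_epochs: int | None = None,
    seed: int = 42,
    L: int | None = None,
    train_kwargs: dict | None = None,
) -> tuple[HybridConfig, HybridModel, pd.DataFrame]:
    """Stage 2: refine the top-k configurations and fit the winner.

    Selection uses refinement-stage validation accuracy, not the short-run
    peak — a short-run high score can collapse under longer optimization.
    The selected configuration is then retrained once on the combined
    training and validation subjects before any test evaluation.
    """
    k = min(k, len(trials))
    L = L or bundles["train"].raw.shape[1]
    kwargs = dict(train_kwargs or {})
    kwargs.setdefault("epochs", long_epochs)
    refined_rows = []
    for rank in range(k):
        row = trials.iloc[rank]
        cfg = _cfg_from_row(row)
        _, model = build_hybrid(cfg, L=L, seed=seed)
        _, hist = train(model, bundles, augment_cfg=AugmentConfig(), seed=seed, **kwargs)
        refined_rows.append(_trial_row(int(row["trial"]), hist.best_val_acc, cfg))
    refined = (
        pd.DataFrame(refined_rows, columns=TRIAL_COLUMNS)
        .sort_values("val_acc", ascending=False)
        .reset_index(drop=True)
    )
    winner_cfg = _cfg_from_row(refined.iloc[0])

    # final fit on train+val; a held-back slice of training windows keeps the
    # callbacks defined without touching test subjects
    trainval = FeatureBundleSet(
        raw=np.concatenate([bundles["train"].raw, bundles["val"].raw]),
        maps=np.concatenate([bundles["train"].maps, bundles["val"].maps]),
        glob=np.concatenate([bundles["train"].glob, bundles["val"].glob]),
        subject_ids=np.concatenate(
            [bundles["train"].subject_ids, bundles["val"].subject_ids]
        ),
        labels=np.concatenate([bundles["train"].labels, bundles["val"].labels]),
        fs=bundles["train"].fs,
    )
    _, final_model = build_hybrid(winner_cfg, L=L, seed=seed)
    final_kwargs = dict(kwargs)
    final_kwargs["epochs"] = final_epochs if final_epochs is not None else kwargs["epochs"]
    train(
        final_model,
        {"train": trainval, "val": bundles["val"]},
        augment_cfg=AugmentConfig(),
        seed=seed,
        **final_kwargs,
    )
    return winner_cfg, final_model, refined
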
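"""Subject-independent splitting, class weighting, training loop, and the
two-stage hyperparameter machinery."""

import numpy as np
import pandas as pd
import pytest

from frontaleeg.features import FeatureBundleSet
from frontaleeg.io_formats import HC, MDD
from frontaleeg.models import HybridConfig, build_hybrid
from frontaleeg.training import (
    SearchSpace,
    class_weights,
    group_split,
    one_hot,
    random_search,
    refine_top_k,
    split_bundles,
    train,
)

L_SMALL = 128


def _subjects(n_hc, n_mdd):
    ids = [f"H{i}" for i in range(n_hc)] + [f"M{i}" for i in range(n_mdd)]
    labels = [HC] * n_hc + [MDD] * n_mdd
    return ids, labels


def _toy_bundles(rng, n_hc=6, n_mdd=6, windows_per_subject=6, separation=3.0):
    """Separable toy cohort: class-shifted glob features and raw offsets."""
    ids, labels = _subjects(n_hc, n_mdd)
    raw, maps, glob, sids, labs = [], [], [], [], []
    for sid, lab in zip(ids, labels):
        shift = separation if lab == MDD else 0.0
        for _ in range(windows_per_subject):
            raw.append(rng.standard_normal((L_SMALL, 3)) + shift * 0.1)
            maps.append(rng.random((3, 8)))
            glob.append(rng.standard_normal(17) + shift)
            sids.append(sid)
            labs.append(lab)
    return FeatureBundleSet(
        raw=np.array(raw), maps=np.array(maps), glob=np.array(glob),
        subject_ids=np.array(sids, dtype=object),
        labels=np.array(labs, dtype=object), fs=250.0,
    )


class TestGroupSplit:
    def test_58_subject_fractions(self):
        ids, labels = _subjects(28, 30)
        split = group_split(ids, labels, seed=42)
        assert len(split.test_subjects) in (11, 12)
        assert len(split.dev_subjects) in (46, 47)
        assert len(split.dev_subjects) + len(split.test_subjects) == 58

    def test_deterministic(self):
        ids, labels = _subjects(10, 10)
        s1 = group_split(ids, labels, seed=3)
        s2 = group_split(ids, labels, seed=3)
        assert s1 == s2

    def test_leakage_audit_bruteforce(self, rng):
        """Window table scan finds zero cross-partition subjects."""
        ids, labels = _subjects(12, 12)
        split = group_split(ids, labels, seed=0)
        window_subjects = np.repeat(np.array(ids, dtype=object), 7)
        partitions = [split.partition_of(s) for s in window_subjects]
        table = pd.DataFrame({"subject": window_subjects, "partition": partitions})
        per_subject = table.groupby("subject")["partition"].nunique()
        assert (per_subject == 1).all()

    def test_many_random_splits_leak_free(self):
        ids, labels = _subjects(15, 14)
        for seed in range(1000):
            split = group_split(ids, labels, seed=seed)
            split.audit(ids)  # raises on any overlap

    def test_missing_class_warns(self):
        ids, labels = _subjects(10, 1)
        with pytest.warns(RuntimeWarning, match="lacks class"):
            group_split(ids, labels, seed=1)


class TestClassWeights:
    def test_balanced(self):
        np.testing.assert_allclose(class_weights([HC] * 100 + [MDD] * 100), [1.0, 1.0])

    def test_paper_test_proportions(self):
        """Inverse-frequency weights for window counts (194 HC, 232 MDD)."""
        w = class_weights([HC] * 194 + [MDD] * 232)
        np.testing.assert_allclose(w, [426 / (2 * 194), 426 / (2 * 232)])
        np.testing.assert_allclose(np.round(w, 3), [1.098, 0.918])
        assert w[0] > 1.0 > w[1]

    def test_scale_invariance(self):
        w1 = class_weights([HC] * 30 + [MDD] * 70)
        w2 = class_weights([HC] * 300 + [MDD] * 700)
        np.testing.assert_allclose(w1, w2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([HC, HC, HC])


class TestTrainLoop:
    def _parts(self, rng):
        bundles = _toy_bundles(rng)
        split = group_split(list(bundles.subject_ids), list(bundles.labels),
                            test_fraction=0.25, val_fraction=0.25, seed=0)
        return split_bundles(bundles, split)

    def test_zero_epochs_returns_initial_weights(self, rng):
        parts = self._parts(rng)
        _, model = build_hybrid(
            HybridConfig(raw_filters=(4, 4, 4), emb_raw=8, head_units=8,
                         map_filters=(4, 8)), L=L_SMALL)
        before = [w.copy() for w in model.get_weights()]
        model, hist = train(model, parts, epochs=0)
        assert hist.val_acc == []
        for b, a in zip(before, model.get_weights()):
            np.testing.assert_array_equal(b, a)

    def test_history_bookkeeping_and_lr_non_increasing(self, rng):
        parts = self._parts(rng)
        _, model = build_hybrid(
            HybridConfig(raw_filters=(4, 4, 4), emb_raw=8, head_units=8,
                         map_filters=(4, 8)), L=L_SMALL)
        model, hist = train(model, parts, epochs=6, batch_size=16, seed=1,
                            plateau_patience=1, early_stop_patience=10)
        n = len(hist.val_acc)
        assert len(hist.train_loss) == len(hist.lr) == n <= 6
        assert all(a >= b for a, b in zip(hist.lr, hist.lr[1:]))
        assert hist.best_val_acc == max(hist.val_acc)

    def test_seeded_determinism(self, rng):
        parts = self._parts(rng)
        accs = []
        for _ in range(2):
            _, model = build_hybrid(
                HybridConfig(raw_filters=(4, 4, 4), emb_raw=8, head_units=8,
                             map_filters=(4, 8)), L=L_SMALL, seed=5)
            _, hist = train(model, parts, epochs=3, batch_size=16, seed=5)
            accs.append(hist.val_acc)
        assert accs[0] == accs[1]

    def test_empty_training_stream_rejected(self, rng):
        parts = self._parts(rng)
        empty = parts["train"].subset(np.zeros(parts["train"].n, dtype=bool))
        _, model = build_hybrid(
            HybridConfig(raw_filters=(4, 4, 4), emb_raw=8, head_units=8,
                         map_filters=(4, 8)), L=L_SMALL)
        with pytest.raises(ValueError, match="empty training"):
            train(model, {"train": empty, "val": parts["val"]}, epochs=1)


class TestSearchSpace:
    def test_matches_published_grid(self):
        space = SearchSpace()
        assert space.emb_raw == (128, 192, 256)
        assert space.lr_init == (5e-4, 8e-4, 1e-3)
        assert space.map_filters == ((32, 64), (48, 96))
        assert space.wd == (5e-5, 1e-4)
        # the selected configuration is a member of the space
        assert space.contains(HybridConfig())

    def test_sampling_without_replacement(self):
        space = SearchSpace()
        configs = space.sample(12, seed=0)
        assert len(configs) == 12
        assert len({tuple(sorted(c.to_dict().items(), key=str)) for c in configs}) == 12
        assert all(space.contains(c) for c in configs)

    def test_sample_clamps_to_space_size(self):
        space = SearchSpace(emb_raw=(128,), head_units=(128,), lr_init=(1e-3,),
                            map_drop=(0.25,), map_filters=((4, 8),),
                            raw_drop=((0.1, 0.1, 0.1),), raw_filters=((4, 4, 4),),
                            wd=(1e-4, 5e-5))
        assert space.size == 2
        assert len(space.sample(12, seed=0)) == 2


@pytest.fixture(scope="module")
def search_setup():
    rng = np.random.default_rng(11)
    bundles = _toy_bundles(rng)
    split = group_split(list(bundles.subject_ids), list(bundles.labels),
                        test_fraction=0.25, val_fraction=0.25, seed=0)
    parts = split_bundles(bundles, split)
    space = SearchSpace(
        emb_raw=(8, 16), head_units=(8,), lr_init=(1e-3,), map_drop=(0.25,),
        map_filters=((4, 8),), raw_drop=((0.1, 0.1, 0.1),),
        raw_filters=((4, 4, 4),), wd=(1e-4,),
    )
    return parts, space


class TestSearchAndRefine:
    def test_table_schema_and_membership(self, search_setup):
        parts, space = search_setup
        trials = random_search(parts, space=space, n_trials=2, seed=1, epochs=2,
                               train_kwargs={"batch_size": 16})
        assert list(trials.columns) == [
            "trial", "val_acc", "emb_raw", "head_units", "lr_init", "map_drop",
            "map_filters", "raw_drop", "raw_filters", "wd",
        ]
        assert len(trials) == 2
        assert trials["val_acc"].is_monotonic_decreasing
        for _, row in trials.iterrows():
            assert row["emb_raw"] in space.emb_raw

    def test_single_trial_table(self, search_setup):
        parts, space = search_setup
        trials = random_search(parts, space=space, n_trials=1, seed=2, epochs=1,
                               train_kwargs={"batch_size": 16})
        assert len(trials) == 1

    def test_refine_selects_by_refinement_accuracy(self, search_setup):
        """The winner is the config with the best refinement-stage validation
        accuracy even if its short-run rank was lower."""
        parts, space = search_setup
        trials = random_search(parts, space=space, n_trials=2, seed=1, epochs=2,
                               train_kwargs={"batch_size": 16})
        cfg, model, refined = refine_top_k(
            trials, parts, k=2, long_epochs=3, final_epochs=2, seed=1,
            train_kwargs={"batch_size": 16})
        assert refined["val_acc"].is_monotonic_decreasing
        winner_row = refined.iloc[0]
        assert cfg.emb_raw == winner_row["emb_raw"]
        # membership audit: winner came from the searched trials
        assert winner_row["trial"] in set(trials["trial"])

    def test_refine_clamps_k(self, search_setup):
        parts, space = search_setup
        trials = random_search(parts, space=space, n_trials=1, seed=3, epochs=1,
                               train_kwargs={"batch_size": 16})
        _, _, refined = refine_top_k(trials, parts, k=5, long_epochs=1,
                                     final_epochs=1, seed=3,
                                     train_kwargs={"batch_size": 16})
        assert len(refined) == 1


class TestConv1DBaselineTraining:
    """The same training loop drives the single-input Conv1D baselines,
    with the SE recipe's augmentations when given an SEAugmentConfig."""

    def test_baselines_train_and_improve(self, rng):
        from frontaleeg.augmentation import SEAugmentConfig
        from frontaleeg.models import build_conv1d_raw, build_conv1d_se

        bundles = _toy_bundles(rng, windows_per_subject=4)
        split = group_split(list(bundles.subject_ids), list(bundles.labels),
                            test_fraction=0.25, val_fraction=0.25, seed=0)
        parts = split_bundles(bundles, split)
        _, raw_model = build_conv1d_raw(L=L_SMALL, seed=0)
        raw_model, hist = train(raw_model, parts, augment_cfg=None, epochs=3,
                                batch_size=16, seed=0)
        assert len(hist.train_loss) == 3
        assert hist.train_loss[-1] < hist.train_loss[0]
        _, se_model = build_conv1d_se(L=L_SMALL, seed=0)
        se_model, hist_se = train(se_model, parts, augment_cfg=SEAugmentConfig(),
                                  epochs=2, batch_size=16, seed=0)
        assert len(hist_se.val_acc) == 2
        probs = se_model.predict_proba(parts["test"].raw)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_one_hot_layout():
    y = one_hot([HC, MDD, HC])
    np.testing.assert_array_equal(y, [[1, 0], [0, 1], [1, 0]])
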
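"""Confusion metrics, Wilson intervals, voting, and effect sizes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frontaleeg.evaluation import (
    ConfusionCounts,
    bootstrap_mean_ci,
    cliffs_delta,
    confusion_metrics,
    majority_vote,
    subject_level_report,
    wilson_ci,
)
from frontaleeg.io_formats import HC, MDD


class TestConfusionMetrics:
    def test_perfect_diagonal(self):
        r = confusion_metrics(ConfusionCounts(tp=10, tn=7, fp=0, fn=0))
        assert r.accuracy == 1.0
        assert r.mcc == 1.0
        assert all(v == 1.0 for v in r.recall.values())

    def test_published_window_table(self):
        # 194 HC windows with 186 correct, 232 MDD windows with 212 correct
        r = confusion_metrics(ConfusionCounts(tp=212, tn=186, fp=8, fn=20))
        assert r.accuracy == pytest.approx(0.9343, abs=5e-5)
        assert r.balanced_accuracy == pytest.approx(0.9363, abs=5e-5)
        assert round(r.mcc, 2) == 0.87
        assert r.recall[HC] == pytest.approx(0.9588, abs=5e-5)
        assert round(r.precision[HC], 2) == 0.90
        assert round(r.precision[MDD], 2) == 0.96

    def test_mcc_equals_phi_coefficient(self, rng):
        """MCC from the closed form matches the Pearson correlation of the
        label/prediction indicator vectors on random tables."""
        for _ in range(300):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            y = np.concatenate(
                [np.ones(tp + fn), np.zeros(tn + fp)]
            )
            yhat = np.concatenate(
                [np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)]
            )
            mcc = confusion_metrics(
                ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
            ).mcc
            if np.std(y) == 0 or np.std(yhat) == 0:
                assert mcc == 0.0
            else:
                assert mcc == pytest.approx(np.corrcoef(y, yhat)[0, 1], abs=1e-12)

    def test_zero_marginal_returns_zero(self):
        assert confusion_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=3)).mcc == 0.0

    def test_weighted_average_uses_support(self):
        r = confusion_metrics(ConfusionCounts(tp=212, tn=186, fp=8, fn=20))
        expected = (r.f1[HC] * 194 + r.f1[MDD] * 232) / 426
        assert r.weighted_avg["f1"] == pytest.approx(expected)


class TestWilson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (398, 426, 0.9066, 0.9541),
            (20, 20, 0.839, 1.0),
            (12, 12, 0.757, 1.0),
            (8, 8, 0.676, 1.0),
        ],
    )
    def test_published_bounds(self, k, n, lo, hi):
        # tolerance is half a unit in the last printed digit (values are
        # printed to 1-2 decimals as percentages)
        got = wilson_ci(k, n)
        assert got[0] == pytest.approx(lo, abs=6e-4)
        assert got[1] == pytest.approx(hi, abs=6e-4)

    def test_symmetry(self):
        lo20, hi20 = wilson_ci(20, 20)
        lo0, hi0 = wilson_ci(0, 20)
        assert hi0 == pytest.approx(1.0 - lo20, abs=1e-12)
        assert lo0 == 0.0

    @given(k=st.integers(0, 200), n=st.integers(1, 200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_brackets_point_estimate(self, k, n):
        k = min(k, n)
        lo, hi = wilson_ci(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(398, 426), (5, 17), (0, 9), (33, 33), (1, 2)]:
            ref = proportion_confint(k, n, alpha=0.05, method="wilson")
            got = wilson_ci(k, n)
            assert got == pytest.approx(ref, abs=1e-10)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestMajorityVote:
    def test_worked_example_7_vs_4(self, rng):
        """Seven MDD votes against four HC votes decide MDD."""
        probs = np.concatenate(
            [np.tile([0.2, 0.8], (7, 1)), np.tile([0.9, 0.1], (4, 1))]
        )
        pred = majority_vote(probs, subject_id="S1")
        assert pred.voted_label == MDD
        assert (pred.votes_mdd, pred.votes_hc) == (7, 4)
        assert pred.confidence == pytest.approx(np.mean(probs[:, 1]))

    def test_tie_resolves_to_hc(self):
        probs = np.array([[0.9, 0.1], [0.1, 0.9], [0.8, 0.2], [0.3, 0.7]])
        assert majority_vote(probs).voted_label == HC

    def test_idempotent_under_duplication(self, rng):
        probs = rng.dirichlet([1, 1], size=9)
        once = majority_vote(probs)
        twice = majority_vote(np.vstack([probs, probs]))
        assert once.voted_label == twice.voted_label
        assert once.confidence == pytest.approx(twice.confidence)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(np.zeros((0, 2)))


class TestSubjectReport:
    def _preds(self, specs):
        return [
            majority_vote(np.tile([0.1, 0.9] if lab == MDD else [0.9, 0.1], (5, 1)),
                          subject_id=sid)
            for sid, lab in specs
        ]

    def test_all_correct_small_cohort_cis(self):
        """Perfect 12 HC + 8 MDD: specificity CI lower bound ~0.757,
        sensitivity lower bound ~0.676."""
        specs = [(f"H{i}", HC) for i in range(12)] + [(f"M{i}", MDD) for i in range(8)]
        truth = dict(specs)
        rep = subject_level_report(self._preds(specs), truth)
        assert rep.accuracy == 1.0
        assert rep.extras["specificity_ci"][0] == pytest.approx(0.757, abs=6e-4)
        assert rep.extras["sensitivity_ci"][0] == pytest.approx(0.676, abs=6e-4)

    def test_order_invariance(self):
        specs = [("A", HC), ("B", MDD), ("C", HC)]
        truth = dict(specs)
        r1 = subject_level_report(self._preds(specs), truth)
        r2 = subject_level_report(self._preds(specs[::-1]), truth)
        assert r1.to_dict() == r2.to_dict()

    def test_missing_label_rejected(self):
        with pytest.raises(KeyError):
            subject_level_report(self._preds([("A", HC)]), {})


class TestEffectSizes:
    def test_cliffs_delta_separated(self):
        assert cliffs_delta([5, 6, 7], [1, 2, 3]) == 1.0
        assert cliffs_delta([1, 2, 3], [5, 6, 7]) == -1.0

    def test_cliffs_delta_identical(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0

    def test_cliffs_delta_matches_bruteforce(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 12))
            y = rng.normal(size=rng.integers(2, 12))
            brute = np.mean([np.sign(xi - yj) for xi in x for yj in y])
            assert cliffs_delta(x, y) == pytest.approx(brute, abs=1e-12)

    def test_bootstrap_constant_vector(self):
        assert bootstrap_mean_ci([3.0, 3.0, 3.0], seed=0) == (3.0, 3.0)

    def test_bootstrap_contains_mean_and_is_deterministic(self, rng):
        vals = rng.normal(size=30)
        lo, hi = bootstrap_mean_ci(vals, seed=5)
        assert lo <= np.mean(vals) <= hi
        assert bootstrap_mean_ci(vals, seed=5) == (lo, hi)

    def test_bootstrap_coverage(self, rng):
        """~95% of intervals over repeated Gaussian draws contain the true mean."""
        hits = 0
        n_rep = 300
        for i in range(n_rep):
            vals = rng.normal(0.0, 1.0, size=25)
            lo, hi = bootstrap_mean_ci(vals, B=500, seed=i)
            hits += lo <= 0.0 <= hi
        assert 0.89 <= hits / n_rep <= 0.99
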
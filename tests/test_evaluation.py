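"""Imbalance-aware metrics, span accuracy and the bootstrap."""

import numpy as np
import pytest
from sklearn.metrics import f1_score

from spin.errors import InputError
from spin.evaluation import (
    bootstrap_span_ci,
    confusion_counts,
    macro_weighted_f1,
    per_class_f1,
    span_accuracy,
    weighted_accuracy,
)
from spin.training import ClassWeights, compute_class_weights


def sklearn_oracle_f1(pred, true, weights):
    """Independent route: per-class F1 from scikit-learn, weighted by hand."""
    f1s = f1_score(true, pred, labels=list(weights.classes), average=None, zero_division=0)
    return float(np.sum(weights.weights * f1s) / np.sum(weights.weights))


def brute_force_weighted_accuracy(pred, true, weights):
    """Independent route: one-vs-rest accuracies tallied sample by sample."""
    pred, true = list(pred), list(true)
    total = 0.0
    for c, w in zip(weights.classes, weights.weights):
        correct = sum(1 for p, t in zip(pred, true) if (p == c) == (t == c))
        total += w * correct / len(true)
    return total / float(np.sum(weights.weights))


class TestConfusionCounts:
    def test_all_correct(self):
        counts = confusion_counts(["a"] * 5 + ["b"] * 5, ["a"] * 5 + ["b"] * 5, ["a", "b"])
        for tp, fp, tn, fn in counts.values():
            assert fp == 0 and fn == 0 and tp + tn == 10

    def test_hand_tally(self):
        counts = confusion_counts(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        assert counts["A"] == (1, 1, 1, 0)  # TP, FP, TN, FN
        assert counts["B"] == (1, 0, 1, 1)

    def test_single_class_degenerate(self):
        counts = confusion_counts(["x"] * 4, ["x"] * 4, ["x"])
        assert counts["x"] == (4, 0, 0, 0)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(InputError):
            confusion_counts(["a"], ["a", "b"], ["a", "b"])


class TestWeightedMetrics:
    def test_perfect_predictions_score_one(self):
        true = ["a"] * 30 + ["b"] * 10
        counts = confusion_counts(true, true, ["a", "b"])
        w = compute_class_weights(true)
        assert macro_weighted_f1(counts, w) == pytest.approx(1.0)
        assert weighted_accuracy(counts, w) == pytest.approx(1.0)

    def test_absent_class_contributes_zero_f1(self):
        # class "c" never true and never predicted in this split
        pred, true = ["a", "b", "a"], ["a", "b", "b"]
        counts = confusion_counts(pred, true, ["a", "b", "c"])
        f1s = per_class_f1(counts)
        assert f1s["c"] == 0.0
        w = ClassWeights(classes=("a", "b", "c"), weights=np.ones(3))
        expected = (f1s["a"] + f1s["b"]) / 3
        assert macro_weighted_f1(counts, w) == pytest.approx(expected)

    def test_matches_independent_oracles_on_random_instances(self, rng):
        for _ in range(50):
            c = int(rng.integers(2, 7))
            n = int(rng.integers(c, 100))
            classes = list(range(c))
            true = np.concatenate([classes, rng.integers(0, c, size=n - c)])
            pred = rng.integers(0, c, size=n)
            w = compute_class_weights(list(true), class_set=classes)
            counts = confusion_counts(list(pred), list(true), classes)
            assert macro_weighted_f1(counts, w) == pytest.approx(
                sklearn_oracle_f1(pred, true, w), abs=1e-12
            )
            assert weighted_accuracy(counts, w) == pytest.approx(
                brute_force_weighted_accuracy(pred, true, w), abs=1e-12
            )

    def test_invariant_to_class_relabeling(self, rng):
        c, n = 4, 80
        true = np.concatenate([np.arange(c), rng.integers(0, c, size=n - c)])
        pred = rng.integers(0, c, size=n)
        w = compute_class_weights(list(true), class_set=range(c))
        counts = confusion_counts(list(pred), list(true), range(c))
        perm = rng.permutation(c)
        true_p = [int(perm[t]) for t in true]
        pred_p = [int(perm[p]) for p in pred]
        w_p = compute_class_weights(true_p, class_set=sorted(perm))
        counts_p = confusion_counts(pred_p, true_p, sorted(perm))
        assert macro_weighted_f1(counts, w) == pytest.approx(
            macro_weighted_f1(counts_p, w_p)
        )
        assert weighted_accuracy(counts, w) == pytest.approx(
            weighted_accuracy(counts_p, w_p)
        )

    def test_balanced_classes_equal_unweighted_counterparts(self, rng):
        for _ in range(50):
            c = int(rng.integers(2, 5))
            per = int(rng.integers(5, 30))
            true = np.repeat(np.arange(c), per)
            pred = rng.integers(0, c, size=c * per)
            w = compute_class_weights(list(true), class_set=range(c))
            counts = confusion_counts(list(pred), list(true), range(c))
            # balanced => weights all 1 => plain macro averages
            assert np.allclose(w.weights, 1.0)
            f1_macro = float(f1_score(true, pred, average="macro", zero_division=0))
            assert macro_weighted_f1(counts, w) == pytest.approx(f1_macro, abs=1e-12)
            assert weighted_accuracy(counts, w) == pytest.approx(
                weighted_accuracy(counts, w, normalization="n_classes"), abs=1e-12
            )


class TestSpanAccuracy:
    def test_tolerance_boundary(self):
        assert span_accuracy([(10, 50)], [(13, 50)], tolerance=3) == (1.0, 1.0)
        assert span_accuracy([(10, 50)], [(14, 50)], tolerance=3)[0] == 0.0

    def test_zero_tolerance_is_exact_match(self):
        pred = [(5, 9), (5, 10)]
        true = [(5, 9), (6, 10)]
        assert span_accuracy(pred, true, tolerance=0) == (0.5, 1.0)

    def test_monotone_in_tolerance(self, rng):
        pred = [tuple(x) for x in rng.integers(0, 50, size=(100, 2))]
        true = [tuple(x) for x in rng.integers(0, 50, size=(100, 2))]
        prev = (0.0, 0.0)
        for tol in range(0, 60, 5):
            cur = span_accuracy(pred, true, tolerance=tol)
            assert cur[0] >= prev[0] and cur[1] >= prev[1]
            prev = cur


class TestBootstrap:
    def test_degenerate_all_hits(self):
        pred = [(10, 20)] * 5
        ci_s, ci_e = bootstrap_span_ci(pred, pred, n_boot=50, seed=1)
        assert (ci_s.mean, ci_s.ci_low, ci_s.ci_high) == (1.0, 1.0, 1.0)
        assert (ci_e.mean, ci_e.ci_low, ci_e.ci_high) == (1.0, 1.0, 1.0)

    def test_same_seed_reproduces_interval(self, rng):
        pred = [tuple(x) for x in rng.integers(0, 30, size=(40, 2))]
        true = [tuple(x) for x in rng.integers(0, 30, size=(40, 2))]
        a = bootstrap_span_ci(pred, true, n_boot=200, seed=9)
        b = bootstrap_span_ci(pred, true, n_boot=200, seed=9)
        assert a == b

    def test_interval_brackets_mean(self, rng):
        pred = [tuple(x) for x in rng.integers(0, 30, size=(60, 2))]
        true = [(p[0] + int(rng.integers(0, 8)), p[1]) for p in pred]
        for ci in bootstrap_span_ci(pred, true, n_boot=300, seed=2):
            assert ci.ci_low <= ci.mean <= ci.ci_high

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InputError):
            bootstrap_span_ci([(1, 2)], [(1, 2)])
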
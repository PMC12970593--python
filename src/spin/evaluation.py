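"""Imbalance-aware metrics, span-boundary accuracy and bootstrap intervals.

Per class c the one-vs-rest confusion counts (TP_c, FP_c, TN_c, FN_c) feed
two weighted summaries under inverse-frequency weights W_c = N / (|C| * s_c)
computed from the *training* supports:

* macro-weighted F1:  sum_c W_c * F1_c / sum_c W_c, with
  F1_c = 2 TP_c / (2 TP_c + FP_c + FN_c) and F1_c = 0 when its denominator
  vanishes;
* weighted accuracy: the W_c-weighted mean of the per-class one-vs-rest
  accuracies (TP_c + TN_c) / (TP_c + TN_c + FP_c + FN_c). Normalisation by
  sum_c W_c (the default) keeps the value in [0, 1] under imbalance; dividing
  by |C| instead is available as ``normalization="n_classes"``.

Domain-boundary accuracy counts a prediction correct when it lies within a
+-tolerance window (3 residues by default) of the annotated boundary,
independently for starts and ends. Uncertainty is summarised by a percentile
bootstrap: the test pairs are resampled with replacement (1000 replicates by
default) and the 2.5/97.5 percentiles of the replicate accuracies bracket
the replicate mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError
from .training import ClassWeights


@dataclass(frozen=True)
class BootstrapCI:
    mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MetricReport:
    """Bundle of the evaluation quantities for one test set."""

    acc_w: float
    f1_mw: float
    per_class_f1: Dict
    start_acc: Optional[float] = None
    end_acc: Optional[float] = None
    tolerance: Optional[int] = None
    start_ci: Optional[BootstrapCI] = None
    end_ci: Optional[BootstrapCI] = None

    def rows(self) -> List[Tuple[str, float]]:
        """Tabular (metric, value) rows for text serialization."""
        out = [("weighted_accuracy", self.acc_w), ("macro_weighted_f1", self.f1_mw)]
        out += [(f"f1[{c}]", v) for c, v in self.per_class_f1.items()]
        if self.start_acc is not None:
            out += [
                (f"span_start_acc(tol={self.tolerance})", self.start_acc),
                (f"span_end_acc(tol={self.tolerance})", self.end_acc),
            ]
        if self.start_ci is not None:
            out += [
                ("span_start_boot_mean", self.start_ci.mean),
                ("span_start_ci_low", self.start_ci.ci_low),
                ("span_start_ci_high", self.start_ci.ci_high),
                ("span_end_boot_mean", self.end_ci.mean),
                ("span_end_ci_low", self.end_ci.ci_low),
                ("span_end_ci_high", self.end_ci.ci_high),
            ]
        return out


def confusion_counts(
    predicted: Sequence, true: Sequence, classes: Sequence
) -> Dict[object, Tuple[int, int, int, int]]:
    """One-vs-rest (TP, FP, TN, FN) tallies per class."""
    predicted, true = list(predicted), list(true)
    if len(predicted) != len(true):
        raise InputError("predicted and true label lists differ in length")
    n = len(true)
    counts = {}
    for c in classes:
        tp = sum(1 for p, t in zip(predicted, true) if p == c and t == c)
        fp = sum(1 for p, t in zip(predicted, true) if p == c and t != c)
        fn = sum(1 for p, t in zip(predicted, true) if p != c and t == c)
        tn = n - tp - fp - fn
        counts[c] = (tp, fp, tn, fn)
    return counts


def per_class_f1(counts: Dict) -> Dict:
    """F1_c = 2 TP / (2 TP + FP + FN); 0 when the denominator is 0."""
    out = {}
    for c, (tp, fp, tn, fn) in counts.items():
        denom = 2 * tp + fp + fn
        out[c] = 2 * tp / denom if denom > 0 else 0.0
    return out


def macro_weighted_f1(counts: Dict, weights: ClassWeights) -> float:
    """Weighted mean of per-class F1 under inverse-frequency weights."""
    w_sum = float(np.sum(weights.weights))
    if w_sum <= 0:
        raise ValueError("sum of class weights must be positive")
    f1s = per_class_f1(counts)
    num = sum(weights[c] * f1s[c] for c in counts)
    return num / w_sum


def weighted_accuracy(
    counts: Dict, weights: ClassWeights, normalization: str = "weight_sum"
) -> float:
    """Weighted mean of per-class one-vs-rest accuracies.

    ``normalization="weight_sum"`` (default) divides by sum_c W_c, keeping
    the score in [0, 1]; ``"n_classes"`` divides by |C| (the two coincide for
    balanced classes, where every W_c = 1).
    """
    w_sum = float(np.sum(weights.weights))
    if w_sum <= 0:
        raise ValueError("sum of class weights must be positive")
    num = 0.0
    for c, (tp, fp, tn, fn) in counts.items():
        total = tp + fp + tn + fn
        acc_c = (tp + tn) / total if total > 0 else 0.0
        num += weights[c] * acc_c
    if normalization == "weight_sum":
        return num / w_sum
    if normalization == "n_classes":
        return num / len(counts)
    raise ValueError(f"unknown normalization {normalization!r}")


def span_accuracy(
    predicted_spans: Sequence[Tuple[int, int]],
    true_spans: Sequence[Tuple[int, int]],
    tolerance: int = 3,
) -> Tuple[float, float]:
    """Fraction of boundaries within +-tolerance, separately for start and end."""
    if len(predicted_spans) != len(true_spans):
        raise InputError("predicted and true span lists differ in length")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pred = np.asarray(predicted_spans, dtype=float)
    true = np.asarray(true_spans, dtype=float)
    hits = np.abs(pred - true) <= tolerance
    return float(hits[:, 0].mean()), float(hits[:, 1].mean())


def bootstrap_span_ci(
    predicted_spans: Sequence[Tuple[int, int]],
    true_spans: Sequence[Tuple[int, int]],
    tolerance: int = 3,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[BootstrapCI, BootstrapCI]:
    """Percentile bootstrap of span accuracy (start, end).

    Resamples the paired test set with replacement ``n_boot`` times and
    reports the replicate mean with the (1-level)/2 percentile interval.
    """
    if len(predicted_spans) < 2:
        raise InputError("need at least 2 span pairs to bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pred = np.asarray(predicted_spans, dtype=float)
    true = np.asarray(true_spans, dtype=float)
    if pred.shape != true.shape:
        raise InputError("predicted and true span lists differ in length")
    hits = (np.abs(pred - true) <= tolerance).astype(float)  # (n, 2)
    n = hits.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = hits[idx].mean(axis=1)  # (n_boot, 2)
    alpha = (1.0 - level) / 2.0
    out = []
    for col in range(2):
        lo, hi = np.percentile(reps[:, col], [100 * alpha, 100 * (1 - alpha)])
        out.append(BootstrapCI(float(reps[:, col].mean()), float(lo), float(hi)))
    return out[0], out[1]


def metric_report(
    predicted_labels,
    true_labels,
    weights: ClassWeights,
    predicted_spans=None,
    true_spans=None,
    tolerance: int = 3,
    n_boot: Optional[int] = None,
    seed: int = 0,
) -> MetricReport:
    """Assemble the full evaluation bundle for one prediction set."""
    counts = confusion_counts(predicted_labels, true_labels, weights.classes)
    kwargs = dict(
        acc_w=weighted_accuracy(counts, weights),
        f1_mw=macro_weighted_f1(counts, weights),
        per_class_f1=per_class_f1(counts),
    )
    if predicted_spans is not None and true_spans is not None:
        s, e = span_accuracy(predicted_spans, true_spans, tolerance)
        kwargs.update(start_acc=s, end_acc=e, tolerance=tolerance)
        if n_boot:
            ci_s, ci_e = bootstrap_span_ci(
                predicted_spans, true_spans, tolerance, n_boot=n_boot, seed=seed
            )
            kwargs.update(start_ci=ci_s, end_ci=ci_e)
    return MetricReport(**kwargs)
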
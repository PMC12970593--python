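"""Canonical synthetic studies: recovery, calibration, abstention, scaling.

These drivers tie the whole pipeline together on generated families with
known ground truth. They are the package's executable demonstrations: the
same functions back the test suite, the acceptance script and the README
examples, so every reported number is recomputed from scratch.

The study training configuration differs from the fine-tuning defaults in
:class:`~spin.training.TrainConfig` (which describe fine-tuning a pretrained
encoder): here small heads are trained from random initialisation over a
frozen deterministic encoder, which calls for a larger learning rate and
more epochs. See docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

import time
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .encoders import EncoderContract, ToyEncoder
from .estimator import SpinClassifier
from .evaluation import metric_report
from .records import ProteinRecord
from .synthetic import FamilySpec, default_motifs, generate_family, shuffled_records
from .training import split_dataset

#: Head-scale optimisation settings for studies over the frozen toy encoder.
STUDY_TRAIN_KWARGS = dict(
    learning_rate=0.1,
    epochs=150,
    weight_decay=0.05,
    dropout=0.2,
    hidden_dim=64,
)


def make_study_family(
    n_classes: int = 3, seed: int = 11, n_per_class: int = 200
) -> Tuple[List[ProteinRecord], List[ProteinRecord], List[ProteinRecord]]:
    """Generate the canonical planted-motif family and split it 80/10/10."""
    spec = FamilySpec(
        motifs=default_motifs(n_classes, seed=seed),
        n_per_class=n_per_class,
        seed=seed,
    )
    records = generate_family(spec)
    return split_dataset(records, seed=seed)


def study_classifier(
    use_span_predictor: bool = True,
    encoder: Optional[EncoderContract] = None,
    random_state: int = 0,
) -> SpinClassifier:
    """A SpinClassifier configured for head-scale training on the toy encoder."""
    return SpinClassifier(
        encoder=encoder or ToyEncoder(),
        use_span_predictor=use_span_predictor,
        random_state=random_state,
        **STUDY_TRAIN_KWARGS,
    )


def synthetic_recovery_study(
    n_classes: int = 3,
    seed: int = 11,
    n_per_class: int = 200,
    n_boot: int = 1000,
    random_state: int = 0,
) -> Dict[str, float]:
    """End-to-end recovery: train on a planted-motif family, evaluate held out.

    Returns the test macro-weighted F1 and weighted accuracy, span boundary
    accuracies at the +-3 tolerance with their bootstrap 95% CIs, the
    span-free (whole-sequence pooling) F1, the fitted temperature with ECE
    before/after, and the abstention statistics against chunk- and
    fully-reshuffled nulls at the suggested confidence threshold.
    """
    from .calibration import confidence_distributions

    train_set, val_set, test_set = make_study_family(n_classes, seed, n_per_class)
    labels = [r.label for r in train_set]

    est = study_classifier(random_state=random_state)
    est.fit(train_set, labels, spans=[r.span for r in train_set], validation_set=val_set)

    true_labels = [r.label for r in test_set]
    pred_spans = [(s.t_start + 1, s.t_end + 1) for s in est.predict_spans(test_set)]
    true_spans = [r.span for r in test_set]
    report = metric_report(
        est.predict(test_set),
        true_labels,
        est.class_weights_,
        predicted_spans=pred_spans,
        true_spans=true_spans,
        tolerance=3,
        n_boot=n_boot,
        seed=random_state,
    )

    est_nospan = study_classifier(use_span_predictor=False, random_state=random_state)
    est_nospan.fit(train_set, labels, validation_set=val_set)
    report_nospan = metric_report(
        est_nospan.predict(test_set), true_labels, est_nospan.class_weights_
    )

    cal = est.calibrate(val_set, [r.label for r in val_set])

    conf_orig = est.predict_proba(test_set).max(axis=1)
    chunk = shuffled_records(test_set, "chunk", seed=random_state + 1)
    full = shuffled_records(test_set, "full", seed=random_state + 1)
    conf_chunk = est.predict_proba(chunk).max(axis=1)
    conf_full = est.predict_proba(full).max(axis=1)
    sep = confidence_distributions(conf_orig, conf_chunk)
    thr = sep.threshold if sep.threshold is not None else 0.8

    return {
        "n_test": len(test_set),
        "f1_macro_weighted": report.f1_mw,
        "weighted_accuracy": report.acc_w,
        "span_start_acc_tol3": report.start_acc,
        "span_end_acc_tol3": report.end_acc,
        "span_start_boot_mean": report.start_ci.mean,
        "span_start_ci_low": report.start_ci.ci_low,
        "span_start_ci_high": report.start_ci.ci_high,
        "span_end_boot_mean": report.end_ci.mean,
        "span_end_ci_low": report.end_ci.ci_low,
        "span_end_ci_high": report.end_ci.ci_high,
        "f1_no_span_predictor": report_nospan.f1_mw,
        "temperature": cal.temperature,
        "ece_before": cal.ece_before,
        "ece_after": cal.ece_after,
        "mean_conf_original": float(conf_orig.mean()),
        "mean_conf_chunk_shuffled": float(conf_chunk.mean()),
        "mean_conf_full_shuffled": float(conf_full.mean()),
        "suggested_threshold": float(thr),
        "original_retained_frac": float((conf_orig >= thr).mean()),
        "chunk_shuffled_abstained_frac": float((conf_chunk < thr).mean()),
        "full_shuffled_abstained_frac": float((conf_full < thr).mean()),
    }


def inference_scaling_study(
    estimator: SpinClassifier,
    base_records: Sequence[ProteinRecord],
    factors: Sequence[int] = (1, 2, 4, 8),
    repeats: int = 5,
) -> Dict[str, float]:
    """Wall time of batched inference vs batch size, with a linear fit.

    The batch at factor f repeats ``base_records`` f times (fixed sequence
    length distribution), the timing per factor is the best of ``repeats``
    runs, and the returned r_squared is from an ordinary least-squares line
    of time against batch size.
    """
    import gc

    sizes, times = [], []
    for f in factors:
        batch = list(base_records) * f
        best = np.inf
        for _ in range(repeats):
            gc.collect()
            gc_was_enabled = gc.isenabled()
            gc.disable()  # keep collector pauses out of the timing
            try:
                t0 = time.perf_counter()
                estimator.predict_proba(batch)
                best = min(best, time.perf_counter() - t0)
            finally:
                if gc_was_enabled:
                    gc.enable()
        sizes.append(len(batch))
        times.append(best)
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(times, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return {
        "sizes": sizes,
        "times": times,
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": 1.0 - ss_res / ss_tot,
    }
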
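"""Scikit-learn-style estimator wrapping the full train/predict pipeline."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import (
    AbstentionDecision,
    classify_with_abstention,
    fit_temperature,
)
from .encoders import EncoderContract, ToyEncoder
from .model import (
    ClassProbabilities,
    ModelConfig,
    RecordFailure,
    SpanPrediction,
    forward,
    pool_span,
    predict_span,
    softmax,
)
from .records import ProteinRecord, tokenize
from .training import Checkpoint, TrainConfig, split_dataset, train


def _as_records(
    X: Sequence[Union[str, ProteinRecord]],
    y: Optional[Sequence] = None,
    spans: Optional[Sequence[Optional[Tuple[int, int]]]] = None,
) -> List[ProteinRecord]:
    records = []
    for i, item in enumerate(X):
        if isinstance(item, ProteinRecord):
            rec = item
            if y is not None:
                rec = ProteinRecord(rec.id, rec.sequence, rec.span, y[i])
            if spans is not None:
                rec = ProteinRecord(rec.id, rec.sequence, spans[i], rec.label)
        else:
            rec = ProteinRecord(
                id=f"seq{i}",
                sequence=str(item).upper(),
                span=spans[i] if spans is not None else None,
                label=y[i] if y is not None else None,
            )
        records.append(rec)
    return records


class SpinClassifier(ClassifierMixin, BaseEstimator):
    """Span-pooled protein functional classifier.

    Predicts a domain span inside each sequence from per-token embeddings of
    a pluggable encoder, mean-pools the span, and assigns one of a fixed set
    of functional classes. Training minimises
    ``0.7 * L_class + 0.3 * L_span`` with inverse-frequency class weights;
    model selection keeps the epoch with the best validation macro-weighted
    F1. Follows the scikit-learn estimator API: ``X`` is a list of amino-acid
    strings (or :class:`ProteinRecord`), ``y`` the class labels; domain spans
    are passed to :meth:`fit` via the ``spans`` keyword as 1-based inclusive
    (start, end) pairs.

    Parameters
    ----------
    encoder : EncoderContract, optional
        Per-token embedding provider; defaults to the deterministic
        :class:`~spin.encoders.ToyEncoder`.
    use_span_predictor : bool
        When False the span module is skipped and the whole-sequence mean
        representation feeds the classifier.
    learning_rate, weight_decay, epochs, batch_size, warmup_frac, dropout
        Optimisation hyperparameters (AdamW, cosine schedule with warmup).
    validation_fraction : float
        Fraction of the training data held out (stratified) for per-epoch
        checkpoint selection.
    random_state : int
        Seed controlling the split, initialisation, shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray
        Class labels in training order.
    checkpoint_ : Checkpoint
        Best-epoch parameter snapshot with configs and the training log.
    class_weights_ : ClassWeights
        Inverse-frequency weights computed from the training supports.
    temperature_ : float
        Softmax temperature (1.0 until :meth:`calibrate` is called).
    """

    def __init__(
        self,
        encoder: Optional[EncoderContract] = None,
        use_span_predictor: bool = True,
        max_length: int = 1024,
        hidden_dim: Optional[int] = None,
        dropout: float = 0.1,
        w_class: float = 0.7,
        learning_rate: float = 1e-4,
        weight_decay: float = 0.01,
        epochs: int = 10,
        batch_size: int = 8,
        eval_batch_size: int = 32,
        warmup_frac: float = 0.10,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.encoder = encoder
        self.use_span_predictor = use_span_predictor
        self.max_length = max_length
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        self.w_class = w_class
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.eval_batch_size = eval_batch_size
        self.warmup_frac = warmup_frac
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, spans: Optional[Sequence] = None, validation_set=None):
        """Train the span and classifier heads.

        ``validation_set`` (list of labeled records) overrides the internal
        stratified hold-out used for checkpoint selection.
        """
        encoder = self.encoder if self.encoder is not None else ToyEncoder()
        records = _as_records(X, y, spans)
        classes = tuple(sorted({r.label for r in records}, key=str))
        model_config = ModelConfig(
            n_classes=len(classes),
            hidden_dim=self.hidden_dim or encoder.dim,
            max_length=self.max_length,
            dropout=self.dropout,
            w_class=self.w_class,
            w_span=1.0 - self.w_class,
            use_span_predictor=self.use_span_predictor,
        )
        train_config = TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            batch_size=self.batch_size,
            eval_batch_size=self.eval_batch_size,
            warmup_frac=self.warmup_frac,
            dropout=self.dropout,
        )
        if validation_set is not None:
            tr, va = list(records), list(validation_set)
        else:
            frac = self.validation_fraction
            tr, va, _ = split_dataset(
                records, (1.0 - frac, frac, 0.0), seed=self.random_state, stratified=True
            )
        ckpt = train(tr, va, encoder, model_config, train_config,
                     seed=self.random_state, classes=classes)
        self.encoder_ = encoder
        self.checkpoint_ = ckpt
        self.classes_ = np.asarray(ckpt.classes, dtype=object)
        self.class_weights_ = ckpt.class_weights
        self.training_log_ = ckpt.training_log
        self.best_epoch_ = ckpt.best_epoch
        self.temperature_ = 1.0
        return self

    @classmethod
    def from_checkpoint(cls, ckpt: Checkpoint, encoder: Optional[EncoderContract] = None):
        """Rebuild a fitted estimator from a checkpoint bundle."""
        est = cls(
            encoder=encoder,
            use_span_predictor=ckpt.model_config.use_span_predictor,
            max_length=ckpt.model_config.max_length,
            hidden_dim=ckpt.model_config.hidden_dim,
            dropout=ckpt.model_config.dropout,
            w_class=ckpt.model_config.w_class,
        )
        est.encoder_ = encoder if encoder is not None else ToyEncoder()
        est.checkpoint_ = ckpt
        est.classes_ = np.asarray(ckpt.classes, dtype=object)
        est.class_weights_ = ckpt.class_weights
        est.training_log_ = ckpt.training_log
        est.best_epoch_ = ckpt.best_epoch
        est.temperature_ = ckpt.temperature
        return est

    # ------------------------------------------------------------- inference
    def _forward(self, X):
        check_is_fitted(self, "checkpoint_")
        records = _as_records(X)
        span_head, clf_head = self.checkpoint_.heads()
        return forward(
            records,
            self.encoder_,
            self.checkpoint_.model_config,
            span_head,
            clf_head,
            temperature=self.temperature_,
        )

    def forward(self, X):
        """Full per-record results: (SpanPrediction, ClassProbabilities),
        with RecordFailure entries in place for unprocessable records."""
        return self._forward(X)

    def predict_logits(self, X) -> np.ndarray:
        """Uncalibrated classifier logits, one row per sequence."""
        check_is_fitted(self, "checkpoint_")
        records = _as_records(X)
        span_head, clf_head = self.checkpoint_.heads()
        cfg = self.checkpoint_.model_config
        out = np.empty((len(records), cfg.n_classes))
        for i, rec in enumerate(records):
            tokens = tokenize(rec, cfg.max_length)
            emb = self.encoder_.embed(tokens)
            if cfg.use_span_predictor and span_head is not None:
                span = predict_span(span_head.logits(emb[1:]))
            else:
                span = None
            pooled = pool_span(emb, span, cfg.use_span_predictor)
            out[i] = clf_head.logits(pooled)[0]
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Calibrated softmax probabilities (temperature applied if fitted)."""
        return softmax(self.predict_logits(X) / self.temperature_, axis=1)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_spans(self, X) -> List[SpanPrediction]:
        """Span predictions in 0-based residue-token indices."""
        out = []
        for item in self._forward(X):
            if isinstance(item, RecordFailure):
                raise item.error
            out.append(item[0])
        return out

    def predict_with_abstention(self, X, threshold: float) -> List[AbstentionDecision]:
        """Selective prediction: label or UNKNOWN by calibrated confidence."""
        probs = self.predict_proba(X)
        decisions = []
        for row in probs:
            d = classify_with_abstention(row, threshold)
            if d.label != "UNKNOWN":
                d = AbstentionDecision(self.classes_[d.label], d.confidence, threshold)
            decisions.append(d)
        return decisions

    # ------------------------------------------------------------ calibration
    def calibrate(self, X, y, n_bins: int = 10):
        """Fit the softmax temperature on a held-out validation set."""
        check_is_fitted(self, "checkpoint_")
        logits = self.predict_logits(X)
        idx = {c: i for i, c in enumerate(self.classes_)}
        labels = np.asarray([idx[lab] for lab in y])
        cal = fit_temperature(logits, labels, n_bins=n_bins)
        self.temperature_ = cal.temperature
        self.checkpoint_.temperature = cal.temperature
        self.calibration_ = cal
        return cal
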
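"""Forward path: span prediction, span pooling and classification heads.

The pipeline per sequence is

    tokenize -> encode (pluggable) -> span logits -> argmax span ->
    mean-pool the span rows (CLS excluded) -> MLP classifier -> softmax.

The span predictor is a single dense layer producing an (L, 2) logit matrix
over the L = N - 1 residue tokens (column 0: start score, column 1: end
score), in the style of extractive question answering. If the predicted end
does not lie strictly after the predicted start, the model falls back to the
whole residue range; no further length or ordering check is applied. The
classifier head is Dropout -> Dense -> Tanh -> Dropout -> Dense -> Softmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .encoders import EncoderContract
from .errors import DegenerateLogitsError, SpinError
from .records import ProteinRecord, tokenize


@dataclass
class ModelConfig:
    """Architecture hyperparameters persisted with every checkpoint."""

    n_classes: int
    hidden_dim: int
    max_length: int = 1024
    n_frozen_layers: int = 6
    dropout: float = 0.1
    w_class: float = 0.7
    w_span: float = 0.3
    use_span_predictor: bool = True

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0.0 < self.w_class < 1.0):
            raise ValueError("w_class must lie strictly between 0 and 1")
        if abs(self.w_class + self.w_span - 1.0) > 1e-9:
            raise ValueError("w_class + w_span must equal 1")


@dataclass(frozen=True)
class SpanPrediction:
    """Predicted domain span in 0-based residue-token indices, inclusive."""

    t_start: int
    t_end: int
    start_conf: float
    end_conf: float
    full_sequence_fallback: bool = False


@dataclass(frozen=True)
class ClassProbabilities:
    """Softmax scores over the functional classes."""

    probs: np.ndarray
    predicted_class: int


@dataclass(frozen=True)
class RecordFailure:
    """Marks a record that could not be processed inside a batch."""

    record_id: str
    error: SpinError


ForwardResult = Tuple[SpanPrediction, ClassProbabilities]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


class SpanHead:
    """Dense layer mapping per-token vectors to (L, 2) start/end logits."""

    def __init__(self, dim: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(dim, 2))
        self.b = np.zeros(2)

    def logits(self, residue_emb: np.ndarray) -> np.ndarray:
        """residue_emb: (L, d) rows for residue tokens only (CLS removed)."""
        return residue_emb @ self.W + self.b

    def parameters(self) -> dict:
        return {"span.W": self.W, "span.b": self.b}


class ClassifierHead:
    """Dropout -> Dense -> Tanh -> Dropout -> Dense classifier over pooled vectors."""

    def __init__(
        self,
        dim: int,
        n_classes: int,
        hidden: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        hidden = hidden or dim
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(dim, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(hidden, n_classes))
        self.b2 = np.zeros(n_classes)

    @property
    def n_classes(self) -> int:
        return self.W2.shape[1]

    def logits(
        self,
        pooled: np.ndarray,
        dropout: float = 0.0,
        rng: Optional[np.random.Generator] = None,
        return_cache: bool = False,
    ):
        """Forward pass; pooled is (B, d). Dropout only when rate > 0 and rng given."""
        x = np.atleast_2d(pooled)
        if dropout > 0.0 and rng is not None:
            m1 = (rng.random(x.shape) >= dropout) / (1.0 - dropout)
            x = x * m1
        else:
            m1 = None
        h_pre = x @ self.W1 + self.b1
        h = np.tanh(h_pre)
        if dropout > 0.0 and rng is not None:
            m2 = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            hd = h * m2
        else:
            m2, hd = None, h
        z = hd @ self.W2 + self.b2
        if not np.all(np.isfinite(z)):
            raise SpinError("non-finite classifier logits")
        if return_cache:
            return z, {"x": x, "m1": m1, "h": h, "m2": m2, "hd": hd}
        return z

    def parameters(self) -> dict:
        return {"clf.W1": self.W1, "clf.b1": self.b1, "clf.W2": self.W2, "clf.b2": self.b2}


def predict_span(span_logits: np.ndarray) -> SpanPrediction:
    """Select the start/end positions with the highest scores.

    Ties break to the lowest index (numpy argmax). If the selected end does
    not lie strictly after the selected start, the prediction falls back to
    the full residue range and is flagged; domain length is not otherwise
    checked.
    """
    logits = np.asarray(span_logits, dtype=float)
    if logits.ndim != 2 or logits.shape[1] != 2:
        raise ValueError("span logits must have shape (L, 2)")
    finite = np.isfinite(logits)
    if not (finite[:, 0].any() and finite[:, 1].any()):
        raise DegenerateLogitsError("all span positions are masked")
    L = logits.shape[0]
    start_scores = np.where(finite[:, 0], logits[:, 0], -np.inf)
    end_scores = np.where(finite[:, 1], logits[:, 1], -np.inf)
    t_start = int(np.argmax(start_scores))
    t_end = int(np.argmax(end_scores))
    start_conf = float(softmax(start_scores)[t_start])
    end_conf = float(softmax(end_scores)[t_end])
    if t_end <= t_start:
        return SpanPrediction(0, L - 1, start_conf, end_conf, full_sequence_fallback=True)
    return SpanPrediction(t_start, t_end, start_conf, end_conf, full_sequence_fallback=False)


def pool_span(
    emb: np.ndarray,
    span: Optional[SpanPrediction],
    use_span_predictor: bool = True,
) -> np.ndarray:
    """Average the residue rows within the predicted span.

    ``emb`` is the full (N, d) matrix including the CLS row, which is removed
    before any indexing and never contributes to the pooled vector. With the
    span predictor disabled, a missing span, or a full-sequence fallback, the
    mean runs over all residue rows.
    """
    residues = np.asarray(emb)[1:]  # drop CLS row before indexing
    L = residues.shape[0]
    if (
        not use_span_predictor
        or span is None
        or span.full_sequence_fallback
    ):
        return residues.mean(axis=0)
    if not (0 <= span.t_start <= span.t_end < L):
        raise IndexError(
            f"span ({span.t_start}, {span.t_end}) outside residue range [0, {L - 1}]"
        )
    return residues[span.t_start : span.t_end + 1].mean(axis=0)


def classify(pooled: np.ndarray, head: ClassifierHead) -> ClassProbabilities:
    """Softmax class probabilities for one pooled vector (dropout disabled)."""
    z = head.logits(pooled)
    probs = softmax(z)[0]
    return ClassProbabilities(probs=probs, predicted_class=int(np.argmax(probs)))


def forward(
    records: Sequence[ProteinRecord],
    encoder: EncoderContract,
    config: ModelConfig,
    span_head: Optional[SpanHead],
    clf_head: ClassifierHead,
    temperature: float = 1.0,
) -> List[Union[ForwardResult, RecordFailure]]:
    """Run the full inference path on a batch of records.

    Per-record errors (empty or over-length sequences) are collected as
    :class:`RecordFailure` entries in place; the batch is never aborted.
    Each sequence is encoded at its own length, so batched processing equals
    one-by-one processing exactly. For domains occurring multiple times only
    the single best-scoring span is reported (argmax of each boundary head).
    """
    results: List[Union[ForwardResult, RecordFailure]] = []
    for rec in records:
        try:
            tokens = tokenize(rec, config.max_length)
        except SpinError as exc:
            results.append(RecordFailure(rec.id, exc))
            continue
        emb = encoder.embed(tokens)
        if config.use_span_predictor and span_head is not None:
            span = predict_span(span_head.logits(emb[1:]))
        else:
            L = tokens.n_residues
            span = SpanPrediction(0, L - 1, 1.0, 1.0, full_sequence_fallback=True)
        pooled = pool_span(emb, span, config.use_span_predictor)
        z = clf_head.logits(pooled) / temperature
        probs = softmax(z)[0]
        results.append(
            (span, ClassProbabilities(probs=probs, predicted_class=int(np.argmax(probs))))
        )
    return results
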
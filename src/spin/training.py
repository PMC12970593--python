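"""Training: weighted multi-loss objective, optimisation and model selection.

The objective combines a class-weighted cross-entropy over functional classes
with a span cross-entropy over start/end positions,

    L = 0.7 * L_class + 0.3 * L_span,

where L_class averages -log p(true class) scaled by the inverse-frequency
weight of the sample's true class, W_c = N / (|C| * s_c), and L_span is the
mean of the start-position and end-position cross-entropies. When span
annotations are absent the span term is dropped. Batch reduction of both
terms is the mean over samples, so the learning rate is batch-size
independent; in mixed batches the span term averages over annotated samples
only.

Optimisation follows AdamW with a cosine-annealed learning rate and linear
warmup over the first 10% of steps. Model selection keeps the epoch with the
highest validation macro-weighted F1 (ties resolve to the earliest epoch).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .encoders import EncoderContract
from .errors import (
    AnnotationError,
    LabelError,
    StratificationError,
    TrainingDivergedError,
    UndefinedWeightError,
)
from .model import (
    ClassifierHead,
    ModelConfig,
    SpanHead,
    log_softmax,
    pool_span,
    predict_span,
    softmax,
)
from .records import ProteinRecord, tokenize

PROB_CLAMP = 1e-12  # floor on probabilities before log


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights W_c = N / (|C| * s_c)."""

    classes: Tuple
    weights: np.ndarray

    def __getitem__(self, cls):
        return float(self.weights[self.classes.index(cls)])

    def as_dict(self) -> Dict:
        return {c: float(w) for c, w in zip(self.classes, self.weights)}


@dataclass(frozen=True)
class LossValue:
    l_class: float
    l_span: Optional[float]
    total: float


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the reference protocol)."""

    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    epochs: int = 10
    batch_size: int = 8
    eval_batch_size: int = 32
    warmup_frac: float = 0.10
    dropout: float = 0.1
    seeds: Tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")


@dataclass
class Checkpoint:
    """Best-epoch parameter snapshot plus configuration and training log."""

    params: Dict[str, np.ndarray]
    model_config: ModelConfig
    train_config: TrainConfig
    classes: Tuple
    class_weights: ClassWeights
    training_log: List[dict]
    best_epoch: int
    seed: int
    temperature: float = 1.0

    def heads(self) -> Tuple[Optional[SpanHead], ClassifierHead]:
        dim = self.params["clf.W1"].shape[0]
        clf = ClassifierHead(dim, self.model_config.n_classes)
        clf.W1 = self.params["clf.W1"].copy()
        clf.b1 = self.params["clf.b1"].copy()
        clf.W2 = self.params["clf.W2"].copy()
        clf.b2 = self.params["clf.b2"].copy()
        span = None
        if "span.W" in self.params:
            span = SpanHead(dim)
            span.W = self.params["span.W"].copy()
            span.b = self.params["span.b"].copy()
        return span, clf


def compute_class_weights(labels: Sequence, class_set: Optional[Sequence] = None) -> ClassWeights:
    """Evaluate W_c = N / (|C| * s_c) from training labels.

    Balanced supports yield all weights exactly 1.
    """
    labels = list(labels)
    classes = tuple(class_set) if class_set is not None else tuple(sorted(set(labels)))
    n = len(labels)
    counts = {c: 0 for c in classes}
    for lab in labels:
        if lab not in counts:
            raise LabelError(f"label {lab!r} outside the configured class set")
        counts[lab] += 1
    for c in classes:
        if counts[c] == 0:
            raise UndefinedWeightError(f"class {c!r} has zero support; W_c is undefined")
    w = np.array([n / (len(classes) * counts[c]) for c in classes], dtype=float)
    return ClassWeights(classes=classes, weights=w)


def classification_loss(
    probs: np.ndarray, labels: Sequence[int], weights: ClassWeights
) -> float:
    """Weighted cross-entropy: mean over the batch of -log p(true) * W(true).

    ``probs`` is (B, |C|); ``labels`` are integer indices into the weight
    vector's class order. Probabilities are clamped at 1e-12 before the log.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs and labels length mismatch")
    if labels.min() < 0 or labels.max() >= len(weights.classes):
        raise LabelError("label index outside class set")
    p_true = np.clip(probs[np.arange(len(labels)), labels], PROB_CLAMP, None)
    w_true = weights.weights[labels]
    return float(np.mean(-np.log(p_true) * w_true))


def span_loss(
    span_logits: Sequence[np.ndarray], true_spans: Sequence[Tuple[int, int]]
) -> float:
    """Mean of start and end cross-entropies, averaged over the batch.

    ``span_logits[i]`` is (L_i, 2); ``true_spans[i]`` are 0-based token
    indices (start, end) over residues.
    """
    if len(span_logits) != len(true_spans):
        raise ValueError("logits and spans length mismatch")
    total = 0.0
    for logits, span in zip(span_logits, true_spans):
        if span is None:
            raise AnnotationError("missing span annotation in a span-mode batch")
        s, e = span
        logits = np.asarray(logits, dtype=float)
        L = logits.shape[0]
        if not (0 <= s < L and 0 <= e < L):
            raise AnnotationError(f"span ({s}, {e}) outside token range [0, {L - 1}]")
        ls = log_softmax(logits[:, 0])
        le = log_softmax(logits[:, 1])
        total += 0.5 * (-ls[s] - le[e])
    return total / len(span_logits)


def total_loss(l_class: float, l_span: Optional[float] = None, w_class: float = 0.7) -> LossValue:
    """Combine the loss terms: w_class * L_class + (1 - w_class) * L_span."""
    if l_class < 0 or (l_span is not None and l_span < 0):
        raise ValueError("loss components must be non-negative")
    if l_span is None:
        return LossValue(l_class, None, l_class)
    return LossValue(l_class, l_span, w_class * l_class + (1.0 - w_class) * l_span)


def split_dataset(
    records: Sequence[ProteinRecord],
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratified: bool = True,
) -> Tuple[List[ProteinRecord], List[ProteinRecord], List[ProteinRecord]]:
    """Deterministic disjoint train/validation/test partition.

    Sizes follow floor(train fraction), floor(validation fraction), remainder
    to test. Stratified mode applies the same rule within each class so class
    proportions are preserved within rounding; every class needs >= 3 members.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    records = list(records)

    def allocate(items: List[ProteinRecord]):
        idx = rng.permutation(len(items))
        n = len(items)
        n_train = int(math.floor(fractions[0] * n))
        n_val = int(math.floor(fractions[1] * n))
        tr = [items[i] for i in idx[:n_train]]
        va = [items[i] for i in idx[n_train : n_train + n_val]]
        te = [items[i] for i in idx[n_train + n_val :]]
        return tr, va, te

    if not stratified:
        return allocate(records)

    by_class: Dict = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    too_small = [c for c, items in by_class.items() if len(items) < 3]
    if too_small:
        raise StratificationError(
            f"classes too small to stratify (need >= 3 members): {sorted(map(str, too_small))}"
        )
    train: List[ProteinRecord] = []
    val: List[ProteinRecord] = []
    test: List[ProteinRecord] = []
    for c in sorted(by_class, key=str):
        tr, va, te = allocate(by_class[c])
        train.extend(tr)
        val.extend(va)
        test.extend(te)
    return train, val, test


def cosine_warmup_lr(step: int, total_steps: int, base_lr: float, warmup_frac: float = 0.10) -> float:
    """Linear warmup over round(warmup_frac * total_steps), then cosine decay to 0."""
    warmup = int(round(warmup_frac * total_steps))
    if warmup > 0 and step < warmup:
        return base_lr * (step + 1) / warmup
    if total_steps <= warmup:
        return base_lr
    progress = (step - warmup) / (total_steps - warmup)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * progress))


class AdamW:
    """Decoupled-weight-decay Adam over a named parameter dict.

    Parameters whose names appear in ``frozen`` are never updated (their
    arrays stay bit-identical), mirroring a frozen/trainable layer split.
    """

    def __init__(
        self,
        params: Dict[str, np.ndarray],
        weight_decay: float = 0.01,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        frozen: Sequence[str] = (),
    ):
        self.params = params
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.frozen = set(frozen)
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        for name, p in self.params.items():
            if name in self.frozen or name not in grads:
                continue
            g = grads[name]
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


def _encode_dataset(records, encoder, max_length):
    """Tokenize and embed every record once; embeddings are reused each epoch."""
    embs, spans, labels = [], [], []
    for rec in records:
        tokens = tokenize(rec, max_length)
        embs.append(encoder.embed(tokens))
        spans.append(rec.span_token_indices())
        labels.append(rec.label)
    return embs, spans, labels


def _evaluate_f1(embs, labels_idx, span_head, clf_head, config, weights) -> Tuple[float, float]:
    """Inference-path macro-weighted F1 and weighted accuracy on a cached set."""
    from .evaluation import confusion_counts, macro_weighted_f1, weighted_accuracy

    preds = []
    for emb in embs:
        if config.use_span_predictor and span_head is not None:
            span = predict_span(span_head.logits(emb[1:]))
        else:
            span = None
        pooled = pool_span(emb, span, config.use_span_predictor)
        z = clf_head.logits(pooled)
        preds.append(int(np.argmax(z[0])))
    classes = list(range(config.n_classes))
    counts = confusion_counts(preds, labels_idx, classes)
    idx_weights = ClassWeights(classes=tuple(classes), weights=weights.weights)
    return (
        macro_weighted_f1(counts, idx_weights),
        weighted_accuracy(counts, idx_weights),
    )


def train(
    train_records: Sequence[ProteinRecord],
    val_records: Sequence[ProteinRecord],
    encoder: EncoderContract,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int = 0,
    classes: Optional[Sequence] = None,
) -> Checkpoint:
    """Train span and classifier heads over a frozen-or-cached encoder.

    Returns the parameter snapshot of the epoch with the highest validation
    macro-weighted F1, together with the full per-epoch training log. Fully
    reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    classes = tuple(classes) if classes is not None else tuple(
        sorted({r.label for r in train_records})
    )
    if len(classes) != model_config.n_classes:
        raise LabelError(
            f"{len(classes)} classes in data but model configured for {model_config.n_classes}"
        )
    cls_index = {c: i for i, c in enumerate(classes)}

    tr_embs, tr_spans, tr_labels = _encode_dataset(train_records, encoder, model_config.max_length)
    va_embs, _, va_labels = _encode_dataset(val_records, encoder, model_config.max_length)
    tr_y = np.array([cls_index[l] for l in tr_labels])
    va_y = [cls_index[l] for l in va_labels]

    weights = compute_class_weights(tr_labels, class_set=classes)

    spans_available = all(s is not None for s in tr_spans)
    use_span = model_config.use_span_predictor and any(s is not None for s in tr_spans)

    dim = encoder.dim
    span_head = SpanHead(dim, rng) if use_span else None
    clf_head = ClassifierHead(dim, model_config.n_classes, hidden=model_config.hidden_dim, rng=rng)

    params: Dict[str, np.ndarray] = dict(clf_head.parameters())
    if span_head is not None:
        params.update(span_head.parameters())
    opt = AdamW(params, weight_decay=train_config.weight_decay)

    n = len(train_records)
    steps_per_epoch = math.ceil(n / train_config.batch_size)
    total_steps = steps_per_epoch * train_config.epochs
    w_c, w_s = model_config.w_class, model_config.w_span

    log: List[dict] = []
    best = {"f1": -np.inf, "epoch": -1, "params": None}
    step = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        ep_lc, ep_ls, ep_tot, n_batches = 0.0, 0.0, 0.0, 0
        for b0 in range(0, n, train_config.batch_size):
            batch = order[b0 : b0 + train_config.batch_size]
            lr = cosine_warmup_lr(step, total_steps, train_config.learning_rate,
                                  train_config.warmup_frac)
            lc, ls = _train_step(
                batch, tr_embs, tr_spans, tr_y, weights, span_head, clf_head,
                params, opt, lr, rng, model_config, train_config, use_span, w_c, w_s,
            )
            tot = total_loss(lc, ls if use_span else None, w_class=w_c).total
            ep_lc += lc
            ep_ls += ls if ls is not None else 0.0
            ep_tot += tot
            n_batches += 1
            step += 1
        f1, acc = _evaluate_f1(va_embs, va_y, span_head, clf_head, model_config, weights)
        if not np.isfinite(f1):
            raise TrainingDivergedError(f"validation F1 became non-finite at epoch {epoch}")
        log.append(
            {
                "epoch": epoch,
                "train_loss_class": ep_lc / n_batches,
                "train_loss_span": (ep_ls / n_batches) if use_span else None,
                "train_loss_total": ep_tot / n_batches,
                "val_f1_mw": f1,
                "val_acc_w": acc,
            }
        )
        # ties keep the latest epoch: the classification metric saturates
        # while the span head is still improving under the shared objective
        if f1 >= best["f1"]:
            best = {"f1": f1, "epoch": epoch,
                    "params": {k: v.copy() for k, v in params.items()}}

    # record the effective span mode: a model trained without annotations
    # runs span-free at inference
    final_config = copy.deepcopy(model_config)
    final_config.use_span_predictor = use_span
    return Checkpoint(
        params=best["params"],
        model_config=final_config,
        train_config=copy.deepcopy(train_config),
        classes=classes,
        class_weights=weights,
        training_log=log,
        best_epoch=best["epoch"],
        seed=seed,
    )


def _train_step(
    batch, tr_embs, tr_spans, tr_y, weights, span_head, clf_head, params, opt,
    lr, rng, model_config, train_config, use_span, w_c, w_s,
):
    """One AdamW step on a mini-batch; returns (l_class, l_span or None)."""
    B = len(batch)
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    # ---- span term (annotated samples only) and pooled vectors -------------
    pooled = np.empty((B, tr_embs[0].shape[1]))
    span_terms = []
    annotated = [i for i in batch if tr_spans[i] is not None] if use_span else []
    n_ann = len(annotated)
    for row, i in enumerate(batch):
        emb = tr_embs[i]
        span = tr_spans[i]
        if use_span and span is not None:
            res = emb[1:]
            logits = span_head.logits(res)
            s, e = span
            ps = softmax(logits[:, 0])
            pe = softmax(logits[:, 1])
            span_terms.append(0.5 * (-np.log(max(ps[s], PROB_CLAMP))
                                     - np.log(max(pe[e], PROB_CLAMP))))
            dcol = np.stack([ps, pe], axis=1)
            dcol[s, 0] -= 1.0
            dcol[e, 1] -= 1.0
            dcol *= w_s * 0.5 / n_ann
            grads["span.W"] += res.T @ dcol
            grads["span.b"] += dcol.sum(axis=0)
            # teacher forcing: pool over the annotated span during training
            pooled[row] = res[s : e + 1].mean(axis=0)
        else:
            pooled[row] = emb[1:].mean(axis=0)

    # ---- classification term ------------------------------------------------
    z, cache = clf_head.logits(pooled, dropout=train_config.dropout, rng=rng,
                               return_cache=True)
    p = softmax(z, axis=1)
    y = tr_y[batch]
    w_true = weights.weights[y]
    l_class = float(np.mean(-np.log(np.clip(p[np.arange(B), y], PROB_CLAMP, None)) * w_true))
    scale = w_c if use_span and n_ann > 0 else 1.0
    dz = p.copy()
    dz[np.arange(B), y] -= 1.0
    dz *= (w_true / B * scale)[:, None]
    grads["clf.W2"] += cache["hd"].T @ dz
    grads["clf.b2"] += dz.sum(axis=0)
    dh = dz @ clf_head.W2.T
    if cache["m2"] is not None:
        dh = dh * cache["m2"]
    dh_pre = dh * (1.0 - cache["h"] ** 2)
    grads["clf.W1"] += cache["x"].T @ dh_pre
    grads["clf.b1"] += dh_pre.sum(axis=0)

    opt.step(grads, lr)
    l_span = float(np.mean(span_terms)) if span_terms else None
    return l_class, l_span


def train_multi_seed(
    train_records,
    val_records,
    encoder,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seeds: Optional[Sequence[int]] = None,
) -> Tuple[List[Checkpoint], Dict[str, float]]:
    """Repeat training across seeds; report mean and standard deviation of the
    best validation macro-weighted F1 (ddof=0 over the seed runs)."""
    seeds = tuple(seeds) if seeds is not None else train_config.seeds
    ckpts = [
        train(train_records, val_records, encoder, model_config, train_config, seed=s)
        for s in seeds
    ]
    f1s = np.array([c.training_log[c.best_epoch]["val_f1_mw"] for c in ckpts])
    summary = {"val_f1_mw_mean": float(f1s.mean()), "val_f1_mw_std": float(f1s.std())}
    return ckpts, summary
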
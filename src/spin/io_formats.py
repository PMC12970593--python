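"""Readers and writers: training CSV, inference FASTA, predictions, checkpoints.

CSV dialect (comma-delimited, header required): columns ``id``, ``sequence``,
optionally ``start`` and ``end`` (1-based inclusive residue coordinates, both
columns present or both absent), optionally ``label``. FASTA files carry
sequences only and are intended for inference; the record id is the first
whitespace-delimited header token. Checkpoints are versioned JSON bundles
holding head parameters, the model/train configuration (including the number
of classes, so inference needs no training data), the per-epoch training log
and the fitted temperature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import CheckpointError, InputError, RowError, SchemaError
from .model import ClassProbabilities, ModelConfig, SpanPrediction
from .records import AMINO_ACIDS, AMBIGUITY, ProteinRecord
from .training import Checkpoint, ClassWeights, TrainConfig

CHECKPOINT_FORMAT_VERSION = 1
_VALID_LETTERS = set(AMINO_ACIDS) | {AMBIGUITY}


def _validate_sequence(seq: str, where: str) -> str:
    seq = str(seq).strip().upper()
    if not seq:
        raise RowError(f"{where}: empty sequence")
    bad = sorted(set(seq) - _VALID_LETTERS)
    if bad:
        raise RowError(
            f"{where}: non-standard letters {bad!r} outside the 20-letter "
            f"alphabet plus ambiguity '{AMBIGUITY}'"
        )
    return seq


def read_training_csv(path: Union[str, Path]) -> List[ProteinRecord]:
    """Read a labeled training table into validated records.

    Span columns are optional table-wide (all rows annotated or none);
    malformed rows raise a row-numbered diagnostic. Line numbers in messages
    count the header as line 1.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "sequence": str})
    for col in ("id", "sequence"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    has_start, has_end = "start" in df.columns, "end" in df.columns
    if has_start != has_end:
        raise SchemaError(f"{path}: span columns must be given as a (start, end) pair")
    has_span = has_start
    has_label = "label" in df.columns
    if df["id"].duplicated().any():
        dups = df["id"][df["id"].duplicated()].tolist()
        raise SchemaError(f"{path}: duplicate sequence ids {dups[:5]!r}")

    records: List[ProteinRecord] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        where = f"{path}:line {line}"
        seq = _validate_sequence(row["sequence"], where)
        span = None
        if has_span:
            s_raw, e_raw = row["start"], row["end"]
            if pd.isna(s_raw) != pd.isna(e_raw):
                raise RowError(f"{where}: start/end must be given together")
            if not pd.isna(s_raw):
                try:
                    s, e = int(s_raw), int(e_raw)
                except (TypeError, ValueError):
                    raise RowError(f"{where}: non-integer span ({s_raw!r}, {e_raw!r})")
                if s > e:
                    raise RowError(f"{where}: start={s} > end={e}")
                if not (1 <= s and e <= len(seq)):
                    raise RowError(
                        f"{where}: span ({s}, {e}) outside sequence of length {len(seq)}"
                    )
                span = (s, e)
        label = None
        if has_label and not pd.isna(row["label"]):
            label = str(row["label"])
        records.append(ProteinRecord(id=str(row["id"]), sequence=seq, span=span, label=label))
    return records


def read_fasta(path: Union[str, Path]) -> List[ProteinRecord]:
    """Read a FASTA file into records (no spans or labels; inference input).

    Duplicate ids are disambiguated with a numeric suffix and a warning;
    an empty file is an error.
    """
    path = Path(path)
    records: List[ProteinRecord] = []
    seen = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id  # first whitespace-delimited header token
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            warnings.warn(f"{path}: duplicate id {rid!r} renamed to {new_id!r}")
            rid = new_id
        else:
            seen[rid] = 1
        seq = _validate_sequence(str(entry.seq), f"{path}:{rid}")
        records.append(ProteinRecord(id=rid, sequence=seq))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def records_from_sequences(sequences: Sequence[str], prefix: str = "seq") -> List[ProteinRecord]:
    """Wrap raw amino-acid strings as records (ids generated)."""
    return [
        ProteinRecord(id=f"{prefix}{i}", sequence=_validate_sequence(s, f"sequence {i}"))
        for i, s in enumerate(sequences)
    ]


def write_predictions(
    records: Sequence[ProteinRecord],
    predictions: Sequence[Tuple[Optional[SpanPrediction], ClassProbabilities]],
    path: Union[str, Path],
    class_names: Sequence,
    input_table: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Write predictions as CSV.

    With ``input_table`` (a CSV that produced ``records``), the output keeps
    every input column and appends ``predicted_class`` and ``probability``.
    Otherwise a fresh table (id, predicted_class, probability, span_start,
    span_end) is written, spans in 1-based inclusive residue coordinates.
    Probabilities are formatted to 6 decimals for deterministic files.
    """
    if len(records) != len(predictions):
        raise InputError("records and predictions are not aligned")
    pred_class = [str(class_names[p.predicted_class]) for _, p in predictions]
    prob = [float(f"{p.probs[p.predicted_class]:.6f}") for _, p in predictions]
    if input_table is not None:
        out = input_table.copy()
        out["predicted_class"] = pred_class
        out["probability"] = prob
    else:
        rows = []
        for rec, (span, p) in zip(records, predictions):
            s = span.t_start + 1 if span is not None else 1
            e = span.t_end + 1 if span is not None else rec.n_residues
            rows.append(
                {
                    "id": rec.id,
                    "predicted_class": str(class_names[p.predicted_class]),
                    "probability": float(f"{p.probs[p.predicted_class]:.6f}"),
                    "span_start": s,
                    "span_end": e,
                }
            )
        out = pd.DataFrame(rows)
    try:
        out.to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:
        raise InputError(f"cannot write predictions to {path}: {exc}") from exc
    return out


def save_checkpoint(ckpt: Checkpoint, path: Union[str, Path]) -> None:
    """Serialize a checkpoint bundle as versioned JSON."""
    payload = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_config": asdict(ckpt.model_config),
        "train_config": asdict(ckpt.train_config),
        "classes": list(map(str, ckpt.classes)),
        "class_weights": ckpt.class_weights.weights.tolist(),
        "params": {k: v.tolist() for k, v in ckpt.params.items()},
        "training_log": ckpt.training_log,
        "best_epoch": ckpt.best_epoch,
        "seed": ckpt.seed,
        "temperature": ckpt.temperature,
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: Union[str, Path]) -> Checkpoint:
    """Load and validate a checkpoint bundle.

    Fails with an explicit incompatibility error on a version mismatch, and
    with a consistency error if the stored class count disagrees with the
    classifier output layer — so tampered or truncated bundles never load.
    """
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointError(
            f"{path}: checkpoint format version {version!r} is incompatible "
            f"with supported version {CHECKPOINT_FORMAT_VERSION}"
        )
    mc = payload["model_config"]
    tc = payload["train_config"]
    tc["seeds"] = tuple(tc.get("seeds", (0, 1, 2)))
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    model_config = ModelConfig(**mc)
    n_out = params["clf.W2"].shape[1]
    if n_out != model_config.n_classes or len(payload["classes"]) != model_config.n_classes:
        raise CheckpointError(
            f"{path}: inconsistent class count (config says {model_config.n_classes}, "
            f"classifier outputs {n_out}, {len(payload['classes'])} class names)"
        )
    # a checkpoint trained without spans must run span-free at inference
    model_config.use_span_predictor = model_config.use_span_predictor and "span.W" in params
    classes = tuple(payload["classes"])
    weights = ClassWeights(classes=classes, weights=np.asarray(payload["class_weights"]))
    return Checkpoint(
        params=params,
        model_config=model_config,
        train_config=TrainConfig(**tc),
        classes=classes,
        class_weights=weights,
        training_log=payload["training_log"],
        best_epoch=payload["best_epoch"],
        seed=payload["seed"],
        temperature=payload.get("temperature", 1.0),
    )


def write_metric_report(report, path: Union[str, Path]) -> None:
    """Serialize a MetricReport as one-row-per-metric TSV plus a JSON sidecar."""
    rows = report.rows()
    path = Path(path)
    with path.open("w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in rows:
            fh.write(f"{name}\t{value:.6f}\n")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({name: value for name, value in rows}, indent=1)
    )
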
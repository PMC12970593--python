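"""Exception hierarchy for the spin package."""


class SpinError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(SpinError):
    """A protein record violates a basic invariant (empty sequence, bad span)."""


class SequenceTooLongError(SpinError):
    """A sequence exceeds the model's maximum length and is excluded.

    Carries the offending record id so callers can log exclusions the way
    over-length sequences are dropped (never truncated) from datasets.
    """

    def __init__(self, record_id: str, length: int, max_length: int):
        self.record_id = record_id
        self.length = length
        self.max_length = max_length
        super().__init__(
            f"sequence {record_id!r} has {length} residues, exceeding the "
            f"{max_length - 1}-residue cap (max_length={max_length} tokens); "
            "over-length sequences are excluded, not truncated"
        )


class DegenerateLogitsError(SpinError):
    """All span positions are masked; no span can be predicted."""


class LabelError(SpinError):
    """A label falls outside the configured class set."""


class AnnotationError(SpinError):
    """A span annotation is missing or invalid in a span-mode batch."""


class UndefinedWeightError(SpinError):
    """A class has zero support, so its inverse-frequency weight is undefined."""


class StratificationError(SpinError):
    """One or more classes are too small to stratify across splits."""


class TrainingDivergedError(SpinError):
    """A validation metric became NaN during training."""


class CalibrationError(SpinError):
    """Temperature optimisation failed to converge."""


class NoSeparationWarning(UserWarning):
    """In-family and out-of-family confidence distributions are identical."""


class SchemaError(SpinError):
    """A tabular input is missing mandatory columns."""


class RowError(SpinError):
    """A tabular input row violates the record invariants."""


class InputError(SpinError):
    """Generic malformed input (empty file, mismatched lengths, ...)."""


class CheckpointError(SpinError):
    """A checkpoint file is incompatible or internally inconsistent."""


class SpecError(SpinError):
    """A synthetic family specification is infeasible."""
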
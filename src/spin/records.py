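"""Protein records and tokenization.

A :class:`ProteinRecord` is the unit of all I/O: a sequence identifier, the
amino-acid string, an optional domain span (1-based inclusive residue
coordinates, the UniProt convention) and an optional functional-class label.

Tokenization prepends a single classification (CLS) token, so a sequence of
``n`` residues becomes ``N = n + 1`` tokens. Sequences longer than
``max_length - 1`` residues are *excluded* (rejected with a signal carrying
the record id), never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import InvalidRecordError, SequenceTooLongError

#: The 20 canonical amino acids, in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Single ambiguity letter; every non-canonical letter tokenizes to this.
AMBIGUITY = "X"

CLS_ID = 0
#: residue ids 1..20 for the canonical letters, 21 for the ambiguity token
TOKEN_IDS = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
AMBIGUITY_ID = 21
VOCAB_SIZE = 22  # CLS + 20 canonical + ambiguity


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with optional span annotation and class label.

    ``span`` is (start, end), 1-based inclusive over residues.
    """

    id: str
    sequence: str
    span: Optional[Tuple[int, int]] = None
    label: Optional[str] = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise InvalidRecordError(f"record {self.id!r}: empty sequence")
        if self.span is not None:
            start, end = self.span
            if not (1 <= start <= end <= len(self.sequence)):
                raise InvalidRecordError(
                    f"record {self.id!r}: span ({start}, {end}) violates "
                    f"1 <= start <= end <= {len(self.sequence)}"
                )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def span_token_indices(self) -> Optional[Tuple[int, int]]:
        """Span as 0-based token indices over residues (CLS removed)."""
        if self.span is None:
            return None
        return self.span[0] - 1, self.span[1] - 1


@dataclass(frozen=True)
class TokenizedSequence:
    """Integer token ids for one sequence, CLS token included."""

    token_ids: np.ndarray  # shape (N,), dtype int64

    @property
    def n_tokens(self) -> int:
        return int(self.token_ids.shape[0])

    @property
    def n_residues(self) -> int:
        return self.n_tokens - 1


def tokenize(record: ProteinRecord, max_length: int = 1024) -> TokenizedSequence:
    """Map a record to token ids: [CLS, residue_1, ..., residue_n].

    Raises
    ------
    InvalidRecordError
        If the sequence is empty (unreachable through ProteinRecord, kept
        for raw-string callers).
    SequenceTooLongError
        If n > max_length - 1. Over-length sequences are excluded from
        processing rather than truncated.
    """
    n = record.n_residues
    if n == 0:
        raise InvalidRecordError(f"record {record.id!r}: empty sequence")
    if n > max_length - 1:
        raise SequenceTooLongError(record.id, n, max_length)
    ids = np.empty(n + 1, dtype=np.int64)
    ids[0] = CLS_ID
    for i, aa in enumerate(record.sequence.upper()):
        ids[i + 1] = TOKEN_IDS.get(aa, AMBIGUITY_ID)
    return TokenizedSequence(ids)
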
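"""Synthetic protein families, null-sequence generators, and helpers.

The family generator plants a class-specific motif inside a compositionally
biased domain, flanked by uniform-random sequence:

    [flank | domain-background ... MOTIF ... domain-background | flank]

Flank residues are i.i.d. uniform over the 20 canonical letters; domain
background residues are drawn from a restricted hydrophobic-leaning alphabet
so that the domain boundary carries a detectable composition step, as real
globular domains do against disordered linkers. Each motif position is
independently substituted with a uniform random letter at the configured
noise rate. True span coordinates (1-based inclusive) and the class label
are recorded on every generated record, so the same dataset exercises span
prediction, classification, weighting, calibration, and abstention.

Two null generators produce out-of-family controls that preserve amino-acid
composition exactly while destroying sequence arrangement: a chunk reshuffle
(contiguous 5-residue blocks permuted within the sequence, trailing short
block kept intact) and a full residue reshuffle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import InputError, SpecError
from .records import AMINO_ACIDS, ProteinRecord

#: Restricted alphabet for domain background residues (hydrophobic core).
DOMAIN_ALPHABET = "ILVM"


def _kmers(s: str, k: int = 3) -> set:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def default_motifs(
    n_classes: int,
    length: int = 12,
    seed: int = 0,
    alphabet: str = DOMAIN_ALPHABET,
) -> List[str]:
    """Composition-matched class motifs over the domain alphabet.

    Every motif is a random permutation of the same balanced multiset of
    domain-alphabet letters, so all classes share one amino-acid composition
    and differ *only* in residue arrangement: classification must read local
    context (k-mers), never letter counts. Drawing motifs from the same
    alphabet as the domain background also keeps the domain compositionally
    homogeneous (no spurious internal boundaries). Motifs are resampled until
    their 3-mer sets are pairwise disjoint, so the classes stay separable by
    local context alone.
    """
    rng = np.random.default_rng(seed)
    base = list((alphabet * (length // len(alphabet) + 1))[:length])
    motifs: List[str] = []
    while len(motifs) < n_classes:
        m = "".join(rng.permutation(base))
        if m not in motifs and all(
            not (_kmers(m) & _kmers(other)) for other in motifs
        ):
            motifs.append(m)
    return motifs


@dataclass
class FamilySpec:
    """Parameters of one synthetic labeled family.

    Defaults reflect the study conditions used throughout the test suite:
    compact domains (20-32 residues) carrying a 12-residue motif, flanks up to
    2x the minimum domain length, 5% per-position motif substitution
    noise, and 200 sequences per class.
    """

    motifs: Sequence[str]
    domain_length: Tuple[int, int] = (20, 32)
    flank_length: Tuple[int, int] = (10, 40)
    noise_rate: float = 0.05
    n_per_class: int = 200
    seed: int = 0
    domain_alphabet: str = DOMAIN_ALPHABET

    def __post_init__(self):
        if len(set(self.motifs)) != len(self.motifs):
            raise SpecError("class motifs must be pairwise distinct")
        if not all(5 <= len(m) <= 12 for m in self.motifs):
            raise SpecError("motif lengths must lie in [5, 12]")
        if self.domain_length[0] < max(len(m) for m in self.motifs):
            raise SpecError("minimum domain length must cover the longest motif")
        if self.domain_length[0] > self.domain_length[1] or self.flank_length[0] > self.flank_length[1]:
            raise SpecError("length ranges must be (min, max) with min <= max")
        if self.flank_length[0] < 0:
            raise SpecError("flank lengths must be non-negative")
        if not (0.0 <= self.noise_rate < 0.5):
            raise SpecError("noise rate must lie in [0, 0.5)")
        if self.n_per_class < 1:
            raise SpecError("need at least one sequence per class")

    @property
    def n_classes(self) -> int:
        return len(self.motifs)

    @property
    def class_labels(self) -> List[str]:
        return [f"class_{i}" for i in range(self.n_classes)]


def _random_letters(rng: np.random.Generator, alphabet: str, n: int) -> str:
    if n == 0:
        return ""
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), size=n)])


def generate_family(spec: FamilySpec) -> List[ProteinRecord]:
    """Generate the labeled family described by ``spec`` (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    records: List[ProteinRecord] = []
    for ci, motif in enumerate(spec.motifs):
        label = spec.class_labels[ci]
        for k in range(spec.n_per_class):
            lf = int(rng.integers(spec.flank_length[0], spec.flank_length[1] + 1))
            rf = int(rng.integers(spec.flank_length[0], spec.flank_length[1] + 1))
            ld = int(rng.integers(spec.domain_length[0], spec.domain_length[1] + 1))
            # motif sits strictly interior to the domain (margin up to 3), so
            # the conserved core never coincides with the annotated boundary
            margin = min(3, (ld - len(motif)) // 2)
            offset = int(rng.integers(margin, ld - len(motif) - margin + 1))
            noised = list(motif)
            for j in range(len(noised)):
                if rng.random() < spec.noise_rate:
                    noised[j] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
            domain = (
                _random_letters(rng, spec.domain_alphabet, offset)
                + "".join(noised)
                + _random_letters(rng, spec.domain_alphabet, ld - offset - len(motif))
            )
            seq = (
                _random_letters(rng, AMINO_ACIDS, lf)
                + domain
                + _random_letters(rng, AMINO_ACIDS, rf)
            )
            records.append(
                ProteinRecord(
                    id=f"{label}_seq{k}",
                    sequence=seq,
                    span=(lf + 1, lf + ld),  # 1-based inclusive
                    label=label,
                )
            )
    return records


def chunk_shuffle(sequence: str, chunk_length: int = 5, seed: int = 0) -> str:
    """Permute contiguous chunks of ``chunk_length`` residues within a sequence.

    The trailing short chunk (when the length is not a multiple of
    chunk_length) is kept intact as its own unit. The amino-acid multiset is
    preserved exactly, so overall composition is unchanged while domain-level
    arrangement is destroyed.
    """
    if chunk_length < 1:
        raise ValueError("chunk_length must be >= 1")
    if len(sequence) == 0:
        raise InputError("cannot shuffle an empty sequence")
    chunks = [sequence[i : i + chunk_length] for i in range(0, len(sequence), chunk_length)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chunks))
    return "".join(chunks[i] for i in order)


def full_shuffle(sequence: str, seed: int = 0) -> str:
    """Uniform random permutation of all residues (composition preserved)."""
    if len(sequence) == 0:
        raise InputError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    letters = list(sequence)
    order = rng.permutation(len(letters))
    return "".join(letters[i] for i in order)


def shuffled_records(
    records: Sequence[ProteinRecord],
    mode: str = "chunk",
    chunk_length: int = 5,
    seed: int = 0,
) -> List[ProteinRecord]:
    """Null-control copies of ``records`` (spans and labels dropped)."""
    out = []
    for i, rec in enumerate(records):
        if mode == "chunk":
            seq = chunk_shuffle(rec.sequence, chunk_length, seed=seed + i)
        elif mode == "full":
            seq = full_shuffle(rec.sequence, seed=seed + i)
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        out.append(ProteinRecord(id=f"{rec.id}|{mode}_shuffled", sequence=seq))
    return out
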
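"""Temperature scaling, expected calibration error and abstention.

Temperature scaling rescales the classifier logits by a single scalar T > 0
fitted on held-out validation data by minimising the negative log-likelihood
of softmax(logits / T). Dividing by a positive scalar is monotone per
sample, so predicted classes never change; only confidence does. Calibration
quality is summarised by the Expected Calibration Error (ECE): samples are
binned by top-class confidence into equal-width bins over (0, 1] and ECE is
the bin-size-weighted mean absolute gap between bin accuracy and bin mean
confidence.

Abstention turns calibrated confidences into selective predictions: a sample
whose top confidence falls below a threshold is labelled UNKNOWN. A
threshold can be suggested from data as the crossing point of the binned
confidence densities of an in-family and an out-of-family (e.g. reshuffled)
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import CalibrationError, InputError, NoSeparationWarning
from .model import ClassProbabilities, log_softmax, softmax

UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class CalibrationModel:
    temperature: float
    ece_before: float
    ece_after: float
    n_bins: int

    def apply(self, logits: np.ndarray) -> np.ndarray:
        """Calibrated probabilities for raw logits."""
        return softmax(np.asarray(logits, dtype=float) / self.temperature, axis=-1)


@dataclass(frozen=True)
class AbstentionDecision:
    label: Union[str, int]
    confidence: float
    threshold: float


@dataclass(frozen=True)
class ConfidenceSeparation:
    """Binned confidence densities of two sets and a suggested threshold."""

    bin_edges: np.ndarray
    density_in: np.ndarray
    density_out: np.ndarray
    threshold: Optional[float]


def _nll(logits: np.ndarray, labels: np.ndarray, temperature: float) -> float:
    ls = log_softmax(logits / temperature, axis=1)
    return float(-np.mean(ls[np.arange(len(labels)), labels]))


def fit_temperature(
    logits: np.ndarray,
    labels: Sequence[int],
    n_bins: int = 10,
    bounds: Tuple[float, float] = (0.05, 20.0),
    tol: float = 1e-4,
) -> CalibrationModel:
    """Fit T on validation logits by bounded 1-D NLL minimisation.

    Already-calibrated logits recover T ~ 1; logits scaled by a factor k
    relative to a calibrated set recover T ~ k. The per-sample argmax is
    unchanged by construction.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if logits.ndim != 2 or logits.shape[1] < 2:
        raise InputError("logits must be (n, C) with C >= 2")
    if len(set(labels.tolist())) < 2:
        raise InputError("need at least 2 classes represented to calibrate")
    # Degenerate case: with every validation sample correctly classified the
    # NLL decreases monotonically as T -> 0 and the optimum saturates at the
    # search bound, collapsing all confidences to 1. The temperature is then
    # unidentified; keep the identity scaling and report it.
    if np.all(np.argmax(logits, axis=1) == labels):
        warnings.warn(
            "validation set is perfectly classified; temperature is "
            "unidentified and left at 1.0",
            UserWarning,
        )
        probs = softmax(logits, axis=1)
        ece = expected_calibration_error(probs, labels, n_bins)
        return CalibrationModel(1.0, ece, ece, n_bins)
    res = minimize_scalar(
        lambda t: _nll(logits, labels, t),
        bounds=bounds,
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise CalibrationError(f"temperature search failed: {res.message}")
    T = float(res.x)
    probs_before = softmax(logits, axis=1)
    probs_after = softmax(logits / T, axis=1)
    assert np.array_equal(np.argmax(probs_before, 1), np.argmax(probs_after, 1))
    return CalibrationModel(
        temperature=T,
        ece_before=expected_calibration_error(probs_before, labels, n_bins),
        ece_after=expected_calibration_error(probs_after, labels, n_bins),
        n_bins=n_bins,
    )


def expected_calibration_error(
    probs: np.ndarray, labels: Sequence[int], n_bins: int = 10
) -> float:
    """Binned |accuracy - confidence| gap, weighted by bin occupancy.

    Bins are equal-width over (0, 1]: bin j collects confidences in
    (j/n_bins, (j+1)/n_bins]. Empty bins contribute 0.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    conf = probs.max(axis=1)
    correct = (np.argmax(probs, axis=1) == labels).astype(float)
    # ceil(conf * n_bins) - 1 maps (0,1] onto bins 0..n_bins-1
    bins = np.clip(np.ceil(conf * n_bins).astype(int) - 1, 0, n_bins - 1)
    n = len(conf)
    ece = 0.0
    for j in range(n_bins):
        mask = bins == j
        if not mask.any():
            continue
        ece += (mask.sum() / n) * abs(correct[mask].mean() - conf[mask].mean())
    return float(ece)


def classify_with_abstention(
    probs: Union[ClassProbabilities, np.ndarray], threshold: float
) -> AbstentionDecision:
    """Return the argmax class, or UNKNOWN when top confidence < threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if isinstance(probs, ClassProbabilities):
        vec = probs.probs
    else:
        vec = np.asarray(probs, dtype=float)
    conf = float(vec.max())
    label: Union[str, int]
    label = UNKNOWN if conf < threshold else int(np.argmax(vec))
    return AbstentionDecision(label=label, confidence=conf, threshold=threshold)


def confidence_distributions(
    in_family_conf: Sequence[float],
    out_family_conf: Sequence[float],
    n_bins: int = 20,
) -> ConfidenceSeparation:
    """Binned top-confidence densities and the lowest density crossing.

    The suggested threshold is the midpoint between the centres of the two
    bins where the sign of (in-density - out-density) flips from negative to
    positive, scanning bins left to right and carrying the last non-zero
    sign across empty or tied bins; the lowest such crossing is returned.
    Identical distributions trigger a no-separation warning and a None
    threshold.
    """
    a = np.asarray(in_family_conf, dtype=float)
    b = np.asarray(out_family_conf, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both confidence sets must be non-empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    d_in, _ = np.histogram(a, bins=edges, density=True)
    d_out, _ = np.histogram(b, bins=edges, density=True)
    diff = d_in - d_out
    if np.allclose(diff, 0.0):
        warnings.warn(
            "in-family and out-of-family confidence distributions are "
            "indistinguishable; no abstention threshold can be suggested",
            NoSeparationWarning,
        )
        return ConfidenceSeparation(edges, d_in, d_out, None)
    centers = 0.5 * (edges[:-1] + edges[1:])
    threshold = None
    last_sign, last_center = 0, None
    for j in range(n_bins):
        if diff[j] == 0.0:
            continue
        sign = 1 if diff[j] > 0 else -1
        if last_sign == -1 and sign == 1:
            threshold = float(0.5 * (last_center + centers[j]))
            break
        last_sign, last_center = sign, centers[j]
    return ConfidenceSeparation(edges, d_in, d_out, threshold)
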
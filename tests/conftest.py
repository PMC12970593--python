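"""Shared fixtures: the canonical synthetic family and trained models.

Training is the expensive step, so the canonical study model (3 balanced
classes, planted 12-residue motifs, 200 sequences per class, 5% motif noise)
is trained once per session and shared by the end-to-end, calibration,
abstention and scaling tests.
"""

import warnings

import numpy as np
import pytest

from spin.studies import make_study_family, study_classifier


@pytest.fixture(scope="session")
def study_data():
    train, val, test = make_study_family(n_classes=3, seed=11)
    return {"train": train, "val": val, "test": test}


@pytest.fixture(scope="session")
def study_model(study_data):
    """Canonical trained and calibrated span-pooled classifier."""
    est = study_classifier(random_state=0)
    train = study_data["train"]
    est.fit(
        train,
        [r.label for r in train],
        spans=[r.span for r in train],
        validation_set=study_data["val"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.calibrate(study_data["val"], [r.label for r in study_data["val"]])
    return est


@pytest.fixture(scope="session")
def study_model_nospan(study_data):
    """Same family, span predictor disabled (whole-sequence pooling)."""
    est = study_classifier(use_span_predictor=False, random_state=0)
    train = study_data["train"]
    est.fit(train, [r.label for r in train], validation_set=study_data["val"])
    return est


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
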
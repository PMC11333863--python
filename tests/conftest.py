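"""Shared fixtures.

Expensive artifacts (the default synthetic cohort and models trained on
it) are session-scoped so the end-to-end, embedding and streaming tests
share one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from fallstream.evaluation import train_and_evaluate
from fallstream.preprocess import segment_cohort, subject_split
from fallstream.synth import generate_cohort
from fallstream.training import TrainConfig

COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    """The study cohort: 10 subjects, 50 falls + 50 ADLs each, 50 Hz."""
    return generate_cohort(10, 50, 50, fs=50.0, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_segments(default_cohort):
    """12 s / 600-sample segments from the default cohort (one per trial)."""
    return segment_cohort(default_cohort.trials, window_s=12.0, fs=50.0)


@pytest.fixture(scope="session")
def default_split(default_segments):
    return subject_split([s.subject_id for s in default_segments], 0.8, COHORT_SEED)


@pytest.fixture(scope="session")
def trained_model(default_segments, default_split):
    """Model trained on the default cohort's training subjects (10 epochs),
    with its held-out-subject evaluation report."""
    cfg = TrainConfig(max_epochs=10, batch_size=128, initial_lr=0.001, seed=COHORT_SEED)
    net, report = train_and_evaluate(
        default_segments, default_split.train_subjects, default_split.test_subjects, cfg
    )
    return net, report


@pytest.fixture(scope="session")
def streaming_model():
    """A model trained on 8 s / 400-sample windows for sliding-window use."""
    cohort = generate_cohort(8, 8, 8, fs=50.0, seed=11)
    segments = segment_cohort(cohort.trials, window_s=8.0, fs=50.0)
    split = subject_split([s.subject_id for s in segments], 0.8, 11)
    cfg = TrainConfig(max_epochs=10, batch_size=16, initial_lr=0.001, seed=11)
    net, report = train_and_evaluate(
        segments, split.train_subjects, split.test_subjects, cfg
    )
    return net, report


@pytest.fixture
def rng():
    return np.random.default_rng(0)
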
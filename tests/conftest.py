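"""Shared fixtures.

The expensive end-to-end artifacts (a trained classifier on the standard
synthetic dataset) are session-scoped so the training-loop tests and the
full-pipeline checks share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecgpipe.model import build_model
from ecgpipe.preprocess import SegmentDataset, split_dataset
from ecgpipe.synth import NoiseSpec, default_templates, generate_record, make_labeled_segments
from ecgpipe.train_eval import TrainConfig, evaluate_model, train_model


@pytest.fixture(scope="session")
def small_segments():
    """120 standardized segments (24/class) for cheap dataset plumbing tests."""
    return make_labeled_segments({c: 24 for c in "NAVLR"}, seed=5)


@pytest.fixture(scope="session")
def clean_n_record():
    """Ten clean normal beats at 60 bpm with truth R indices."""
    record, r_idx, labels = generate_record(["N"] * 10, heart_rate=60, seed=3)
    return record, r_idx, labels


@pytest.fixture(scope="session")
def e2e_run():
    """One full scaled-down run: 500 segments/class, lr 0.001, batch 150.

    Returns (trained model, history, test EvalReport, test arrays).
    Training is capped at 12 epochs; the classifier converges on this
    separable dataset well before that.
    """
    segments = make_labeled_segments({c: 500 for c in "NAVLR"}, seed=11)
    dataset = SegmentDataset(segments=segments, provenance={"seed": 11})
    train_set, val_set, test_set = split_dataset(dataset, 0.7, 0.1, seed=0)
    model = build_model(seed=0)
    config = TrainConfig(learning_rate=0.001, batch_size=150, max_epochs=12,
                         early_stop_patience=6, seed=0)
    model, history = train_model(model, train_set, val_set, config)
    report = evaluate_model(model, test_set)
    return model, history, report, test_set
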
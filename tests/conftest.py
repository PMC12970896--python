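"""Shared fixtures: small seeded synthetic datasets reused across tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import eegmark as em


@pytest.fixture(scope="session")
def small_dataset() -> em.SynthDataset:
    """Three-state synthetic dataset, small enough for fast CV tests."""
    return em.generate_dataset(12, duration_s=12.0, master_seed=11)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Base-feature table for the small dataset (one row per window)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return em.extract_features(small_dataset.recordings,
                                   warn_uncalibrated=False)


@pytest.fixture(scope="session")
def small_labels(small_dataset):
    return {r.recording_id: r.label for r in small_dataset.recordings}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
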
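"""Shared fixtures: small synthetic campaigns reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from metaldecoder.core_io import Metal
from metaldecoder.features import fit_pca, project
from metaldecoder.pipeline import split_dataset
from metaldecoder.preprocess import preprocess_dataset
from metaldecoder.syndata import simulate_dataset, small_layout_config


@pytest.fixture(scope="session")
def cr_small_dataset():
    """100 spectra/class chromium campaign (9 decades + control), raw."""
    return simulate_dataset(small_layout_config(Metal.CR6, seed=11))


@pytest.fixture(scope="session")
def cr_preprocessed(cr_small_dataset):
    return preprocess_dataset(cr_small_dataset)


@pytest.fixture(scope="session")
def cr_features(cr_preprocessed):
    """(train, holdout) score matrices: split, PCA fit on train, both projected."""
    train_ds, hold_ds = split_dataset(cr_preprocessed, 0.2, seed=7)
    basis = fit_pca(train_ds, n_components=22)
    return project(train_ds, basis), project(hold_ds, basis)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
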
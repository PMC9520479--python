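"""Shared fixtures: synthetic study datasets preprocessed once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ramanbiopsy import (
    GroupedMatrix,
    generate_dataset,
    paper_like_config,
    preprocess_pipeline,
    zero_contrast_config,
)

DATASET_SEED = 1


@pytest.fixture(scope="session")
def paper_dataset():
    """Raw emulated-study dataset: 3/3/4 samples x 5 replicates, two
    saturated replicates (one normal, one center)."""
    return generate_dataset(paper_like_config(DATASET_SEED))


@pytest.fixture(scope="session")
def paper_processed(paper_dataset):
    """Fully preprocessed study dataset (14/15/19 spectra, 683 points)."""
    measurements, backgrounds, _ = paper_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess_pipeline(measurements, backgrounds)


@pytest.fixture(scope="session")
def paper_matrix(paper_processed) -> GroupedMatrix:
    return GroupedMatrix.from_spectrum_set(paper_processed)


@pytest.fixture(scope="session")
def null_matrix() -> GroupedMatrix:
    """Preprocessed dataset with all class contrasts set to zero."""
    measurements, backgrounds, _ = generate_dataset(
        zero_contrast_config(DATASET_SEED))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed = preprocess_pipeline(measurements, backgrounds)
    return GroupedMatrix.from_spectrum_set(processed)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
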
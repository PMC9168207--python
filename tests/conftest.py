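"""Shared fixtures: phantoms, preprocessed images and feature matrices.

The full 51 + 61 phantom dataset and its feature matrices are expensive, so
they are computed once per session and shared by the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from echocad.phantom import PhantomConfig, generate_dataset, generate_phantom
from echocad.preprocess import preprocess_frame
from echocad.transforms import get_extractor

MASTER_SEED = 17


@pytest.fixture(scope="session")
def phantom_config() -> PhantomConfig:
    return PhantomConfig(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def single_phantom(phantom_config):
    """One HTN phantom with its default overlay (fast unit-test input)."""
    return generate_phantom(phantom_config, "htn", 42)


@pytest.fixture(scope="session")
def echo_image(single_phantom):
    """A fully preprocessed 512x512 image."""
    return preprocess_frame(single_phantom.image)


@pytest.fixture(scope="session")
def full_dataset(phantom_config):
    """The default 51 normal + 61 HTN phantom dataset."""
    return generate_dataset(phantom_config, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def preprocessed_images(full_dataset):
    images = np.stack([preprocess_frame(r.image).pixels for r in full_dataset])
    labels = np.array([r.label for r in full_dataset])
    return images, labels


@pytest.fixture(scope="session")
def cntlet_matrix(preprocessed_images):
    images, labels = preprocessed_images
    return get_extractor("cntlet").transform(images), labels


@pytest.fixture(scope="session")
def shelet_matrix(preprocessed_images):
    images, labels = preprocessed_images
    return get_extractor("shelet").transform(images), labels


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
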
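"""Shared fixtures: tiny configurations and datasets kept deliberately
small so the whole suite runs on one CPU."""

import numpy as np
import pytest

from leafnet import ModelConfig, build_variant
from leafnet.datapipe import Dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest legal full variant: 32 px input, quarter width."""
    return ModelConfig(input_size=32, width_multiplier=0.25, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    """Randomly initialized full variant (deterministic weights)."""
    return build_variant(tiny_config)


@pytest.fixture(scope="session")
def tiny_images():
    rng = np.random.default_rng(7)
    return rng.random((6, 32, 32, 3)).astype(np.float32)


def make_random_dataset(counts, size=8, seed=0, split=None):
    """Random-pixel dataset with exact per-class counts (content-light
    stand-in where only labels and bookkeeping matter)."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cls, count in enumerate(counts):
        for _ in range(count):
            images.append(rng.random((size, size, 3)).astype(np.float32))
            labels.append(cls)
    order = rng.permutation(len(images))
    tags = [split] * len(images) if split else None
    return Dataset([images[i] for i in order], np.asarray(labels)[order], tags)
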
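"""Shared fixtures: synthetic datasets and a session-scoped trained model."""

from __future__ import annotations

import numpy as np
import pytest

from chipcell import detector
from chipcell.synthgen import SceneSpec, make_chamber_scene, random_scenes

# 4 training images totalling exactly 40 cell annotations
TRAIN_QUAD = [
    ("medium_double", 8),
    ("large_triple", 14),
    ("wide_single", 8),
    ("large_triple", 10),
]


def make_training_quad(seed: int = 1):
    rng = np.random.default_rng(seed)
    return [
        make_chamber_scene(
            SceneSpec(
                chamber_type=ct,
                n_cells=n,
                target_rsd=float(rng.uniform(0.15, 0.27)),
                blur_sigma_px=float(rng.uniform(0.0, 1.0)),
                seed=int(rng.integers(2**31)),
            )
        )
        for ct, n in TRAIN_QUAD
    ]


@pytest.fixture(scope="session")
def train_images():
    return make_training_quad(seed=1)


@pytest.fixture(scope="session")
def trained_model(train_images):
    model, history = detector.train(train_images, detector.TrainConfig(seed=0))
    return model, history


@pytest.fixture(scope="session")
def test_scenes():
    return random_scenes(20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
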
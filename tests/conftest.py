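from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cattlecount as cc

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> cc.RunConfig:
    return cc.RunConfig()


@pytest.fixture(scope="session")
def oracle_config() -> cc.RunConfig:
    return cc.RunConfig(classifier="oracle")


@pytest.fixture(scope="session")
def small_scene():
    """A 896×896 pasture with five isolated adults (session-cached)."""
    spec = cc.SceneSpec(n_animals=5, width=896, height=896)
    img, truth = cc.generate_scene(spec, seed=11)
    return spec, img, truth


@pytest.fixture(scope="session")
def small_roi(small_scene, config):
    _, img, truth = small_scene
    grid = cc.tile_image(img, config.tile_size)
    clf = cc.truth_oracle_classifier(truth)
    return cc.build_roi(img, grid, clf)


def uniform_roi(value, shape=(64, 64)) -> cc.RoiImage:
    """An RoiImage with every pixel at the given RGB value, full ROI."""
    px = np.full(shape + (3,), value, dtype=np.uint8)
    return cc.RoiImage(pixels=px, roi_mask=np.ones(shape, dtype=bool))
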
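import numpy as np
import pytest

from wheatlai import BandSet, SceneConfig, generate_scene, texture_stack


@pytest.fixture(scope="session")
def small_config():
    return SceneConfig(width=128, height=128, seed=11, n_points=60)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def small_bands(small_bundle):
    return BandSet.from_scene(small_bundle.scene)


@pytest.fixture(scope="session")
def small_stack(small_bands):
    return texture_stack(small_bands)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
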
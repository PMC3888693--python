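import numpy as np
import pytest

from rnfltex.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A fast desk-scale scene used by most integration-style tests."""
    return generate_scene(SceneConfig(seed=3, fundus_size=(288, 288), slo_size=(192, 192)))


@pytest.fixture(scope="session")
def default_scene():
    """A scene at the generator's default geometry."""
    return generate_scene(SceneConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
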
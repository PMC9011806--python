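import numpy as np
import pytest

from dese.encoding import SpeedDistribution
from dese.flow import CameraModel, ClutteredScene, GroundPlaneScene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_camera():
    return CameraModel(grid=16)


@pytest.fixture
def cluttered_scene():
    return ClutteredScene(seed=7)


@pytest.fixture
def ground_scene():
    return GroundPlaneScene()


@pytest.fixture
def uniform_dist():
    return SpeedDistribution.uniform(0.0, 50.0, bins=500)
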
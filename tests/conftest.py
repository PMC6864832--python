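import numpy as np
import pytest

from gazerange.head_pose import calibrate
from gazerange.synthetic_scene import (
    default_scene,
    make_templates,
    render_frame,
    session_config_for,
)


@pytest.fixture(scope="session")
def scene():
    return default_scene()


@pytest.fixture(scope="session")
def templates():
    return make_templates()


@pytest.fixture(scope="session")
def config(scene):
    return session_config_for(scene)


@pytest.fixture(scope="session")
def calibration(scene, templates, config):
    frames = [render_frame((0.0, 0.0, 0.0), scene, templates) for _ in range(3)]
    return calibrate(frames, templates, config.layout, config.similarity_threshold)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
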
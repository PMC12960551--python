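import numpy as np
import pytest

from footmetry.morphometry import measure_foot
from footmetry.synthetic_foot import FootParams, generate_foot


@pytest.fixture(scope="session")
def default_params():
    return FootParams()


@pytest.fixture(scope="session")
def foot_scene(default_params):
    """Phantom foot at working resolution with ground-truth landmarks."""
    return generate_foot(default_params, resolution=32, seed=1)


@pytest.fixture(scope="session")
def foot_report(foot_scene):
    mesh, landmarks = foot_scene
    return measure_foot(mesh, landmarks)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
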
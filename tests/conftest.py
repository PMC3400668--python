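import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20120719)


@pytest.fixture
def triangle():
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])


def similarity_transform(coords, angle=0.7, scale=2.3, shift=(5.0, -3.0)):
    """Apply rotation + scaling + translation to a (k, 2) configuration."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return scale * coords @ rot.T + np.asarray(shift)
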
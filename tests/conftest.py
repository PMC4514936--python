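import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150725)


def random_triad_coords(rng, scale=30.0, min_area=5.0):
    """Random well-conditioned triad coordinates (3x3)."""
    from splintacc.geometry import triangle_area

    while True:
        coords = rng.uniform(-scale, scale, size=(3, 3))
        if triangle_area(coords) > min_area:
            return coords


def random_rotation_matrix(rng, max_deg=25.0):
    """Random small proper rotation via the package Euler convention."""
    from splintacc.pose import euler_to_matrix

    p, r, y = rng.uniform(-max_deg, max_deg, size=3)
    return euler_to_matrix(p, r, y)
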
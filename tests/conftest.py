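import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def substrate():
    from trophomech.fttc import ElasticSubstrate

    return ElasticSubstrate()


@pytest.fixture(scope="session")
def piv_cfg():
    from trophomech.piv import PIVConfig

    return PIVConfig()


def rotate_vector_field(fx, fy):
    """+90-degree rotation of a square-lattice vector field (image frame,
    y down): positions via rot90(. , -1), components (x, y) -> (-y, x)."""
    return -np.rot90(fy, -1), np.rot90(fx, -1)


@pytest.fixture(scope="session")
def uniform_shift_pair():
    """Bead image pair with a known uniform 5 px x-shift (session-cached:
    used by unit and acceptance tests)."""
    from trophomech.synthetic import BeadImageSpec, make_bead_pair

    spec = BeadImageSpec(image_size=(384, 384), seed=11)
    ref, cur, truth = make_bead_pair(
        spec, lambda x, y: (np.full_like(x, 5.0), np.zeros_like(y))
    )
    return ref, cur, truth
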
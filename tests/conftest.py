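import numpy as np
import pytest
from hypothesis import settings

from plaquer1.phantom import (
    B1Field,
    PhantomSpec,
    PlaqueBlob,
    build_ground_truth,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

CANONICAL_DELAYS = np.array([77.0, 200.0, 350.0, 500.0, 1200.0])
CANONICAL_TR = 1500.0


@pytest.fixture(scope="session")
def delays():
    return CANONICAL_DELAYS


@pytest.fixture(scope="session")
def tr():
    return CANONICAL_TR


def small_plaque_spec(**overrides) -> PhantomSpec:
    """A compact single-plaque phantom used across test modules."""
    defaults = dict(
        grid_shape=(24, 24, 8),
        voxel_size=(0.14, 0.14, 0.22),
        plaques=(PlaqueBlob(center_mm=(0.53, 0.0, 0.0), semi_axes_mm=(0.3, 0.24, 0.4)),),
        gd_concentration={"lumen": 0.0, "wall": 0.0, "plaque": 0.1, "background": 0.0},
        seed=11,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture()
def plaque_spec():
    return small_plaque_spec()


@pytest.fixture()
def plaque_truth(plaque_spec):
    return build_ground_truth(plaque_spec)


@pytest.fixture()
def flat_b_spec():
    """Same phantom with perfect saturation everywhere (B identically 0)."""
    return small_plaque_spec(b1_field=B1Field(mean=0.0, amplitude=0.0))
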
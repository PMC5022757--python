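import numpy as np
import pytest

from dticond import (
    PhantomSpec,
    TissueModel,
    default_scheme,
    make_limb_phantom,
)

# small grid matching the default 240x240x80 mm field of view
SMALL_GRID = dict(grid_shape=(24, 24, 8), voxel_size=(10.0, 10.0, 10.0))


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(**SMALL_GRID, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_limb_phantom(small_spec)


@pytest.fixture(scope="session")
def coherent_spec():
    """Phantom whose tissues each have a single fixed fiber orientation."""
    return PhantomSpec(
        **SMALL_GRID,
        muscle=TissueModel((1.7e-3, 0.2e-3, 0.2e-3), (0, 0, 1)),
        tumor=TissueModel((1.4e-3, 0.5e-3, 0.5e-3), (0, 0, 1)),
        bone=TissueModel((0.6e-3, 0.25e-3, 0.25e-3), (0, 0, 1)),
        seed=7,
    )


@pytest.fixture(scope="session")
def scheme12():
    return default_scheme(n_directions=12)
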
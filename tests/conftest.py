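import numpy as np
import pytest

import smlmclem as sm


@pytest.fixture(scope="session")
def default_camera() -> sm.CameraModel:
    return sm.CameraModel()


@pytest.fixture(scope="session")
def default_psf() -> sm.PSFModel:
    return sm.PSFModel()


@pytest.fixture(scope="session")
def membrane_pair_emitters() -> sm.EmitterSet:
    """Two parallel membranes 300 nm apart, densely labeled."""
    return sm.generate_structure(
        "membrane_pair",
        {"spacing": 300.0, "length": 3000.0, "density_per_um": 3000.0},
        field_of_view=(4000.0, 4000.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def uniform_points() -> np.ndarray:
    """Uniform Poisson field at 10,000 points/um^2 in a 2x2 um square."""
    rng = np.random.default_rng(11)
    n = rng.poisson(10000 * 4.0)
    return rng.uniform(0.0, 2000.0, size=(n, 2))
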
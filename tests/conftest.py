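import numpy as np
import pytest

from lumifuse import (
    DegradationSpec,
    Hypercube,
    NetworkConfig,
    PhantomSpec,
    WavelengthGrid,
    generate_phantom,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture()
def small_grid():
    """31 evenly spaced bands over 400-1000 nm (20 nm spacing)."""
    return WavelengthGrid.linear(400.0, 1000.0, 31)


@pytest.fixture()
def random_cube(rng, small_grid):
    """Random float32 reflectance cube, 16x16x31."""
    data = rng.random((16, 16, 31), dtype=np.float32)
    return Hypercube(data, small_grid, patient_id="P000", name="rand")


@pytest.fixture()
def phantom_sample():
    return generate_phantom(PhantomSpec(64, 64, n_bands=31, seed=11))


@pytest.fixture()
def default_degradation():
    return DegradationSpec()


@pytest.fixture()
def net_config(small_grid):
    return NetworkConfig.from_wavelengths(small_grid)
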
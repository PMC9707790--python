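import numpy as np
import pytest

from colonyseg.fixtures import ColonyParams, generate_colony


@pytest.fixture(scope="session")
def colony30():
    """A dense phase-contrast colony with touching rods."""
    return generate_colony(ColonyParams(n_cells=30, packing="colony", seed=7))


@pytest.fixture(scope="session")
def small_colony():
    return generate_colony(
        ColonyParams(image_height=128, image_width=128, n_cells=10, seed=3)
    )


@pytest.fixture
def two_squares():
    """Two 4x4 instances sharing an edge."""
    m = np.zeros((10, 10), np.uint16)
    m[3:7, 1:5] = 1
    m[3:7, 5:9] = 2
    return m
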
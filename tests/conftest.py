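import numpy as np
import pytest

from flowadhesion import (
    CellMorphology,
    ChannelGeometry,
    FluidProperties,
)

# Reference flow-cell operating point used throughout the tests: 0.8 x 1.6 cm
# channel, mid-channel observation, citrate buffer, E. coli suspension.
GEOMETRY = ChannelGeometry(width=0.016, height=0.008, length=0.2542, axial_position=0.1271)
FLUID = FluidProperties(
    density=993.37, viscosity=6.94e-4, diffusion_coefficient=4.0e-13, cell_concentration=7.6e13
)
CELL = CellMorphology(equivalent_radius=4.5e-7)

FLOW_RATES_ML_S = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
SHEAR_RATES_S = (7.5, 15.0, 33.7, 51.6, 80.3, 100.8)

PIXEL_SCALE_UM = 0.61


@pytest.fixture
def geometry():
    return GEOMETRY


@pytest.fixture
def fluid():
    return FLUID


@pytest.fixture
def cell():
    return CELL


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
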
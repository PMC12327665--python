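import numpy as np
import pytest

from rptsim import (FlowParameters, GrowthParams, LatticeGrid, couple,
                    default_patient, grow_network, make_taf_field,
                    table2_patients)


@pytest.fixture(scope="session")
def patient():
    return default_patient()


@pytest.fixture(scope="session")
def patients():
    return table2_patients()


@pytest.fixture(scope="session")
def small_grid():
    """Desk-scale lattice: 20 mm domain at 400 um spacing, 16 mm tumor."""
    return LatticeGrid(nx=51, ny=51, h=400e-6)


@pytest.fixture(scope="session")
def small_taf(small_grid):
    return make_taf_field(small_grid)


@pytest.fixture(scope="session")
def small_net(small_grid, small_taf):
    return grow_network(small_grid, small_taf, GrowthParams(), seed=7)


@pytest.fixture(scope="session")
def small_pressure(small_net, small_grid):
    return couple(small_net, small_grid, FlowParameters())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
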
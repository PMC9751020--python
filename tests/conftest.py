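import numpy as np
import pytest

from tfusim.head_model import HeadGeometryConfig, build_head_map, build_transducer_source
from tfusim.acoustic_solver import simulate
from tfusim.sonophore_neuron import BLSParams, RSNeuronParams, build_lookup_table
from tfusim.sonophore_neuron.bls import build_pm_interpolant


@pytest.fixture(scope="session")
def bls():
    return BLSParams()


@pytest.fixture(scope="session")
def neuron():
    return RSNeuronParams()


@pytest.fixture(scope="session")
def pm(bls):
    return build_pm_interpolant(bls)


@pytest.fixture(scope="session")
def table_small(bls, neuron, pm):
    """Lookup table over PA {0, 50, 100, 150} kPa, full Qm axis."""
    return build_lookup_table(
        bls, 250e3, pa_grid=np.array([0.0, 50e3, 100e3, 150e3]),
        neuron=neuron, pm=pm,
    )


@pytest.fixture(scope="session")
def coarse_geometry():
    """1 mm head grid used by the solver-backed integration tests."""
    return HeadGeometryConfig(grid_nx=281, grid_ny=281, dx=1e-3)


@pytest.fixture(scope="session")
def coarse_head_solution(coarse_geometry):
    """One solved head condition (skull 5.4 mm, DC 90%) shared by tests."""
    medium = build_head_map(coarse_geometry)
    source = build_transducer_source(coarse_geometry, 0.9, 500e-6)
    field = simulate(medium, source)
    return coarse_geometry, medium, field
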
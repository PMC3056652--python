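import numpy as np
import pytest

import panfate as pf


@pytest.fixture(scope="session")
def network():
    return pf.build_master_network()


@pytest.fixture(scope="session")
def params():
    return pf.ParameterSet()


@pytest.fixture(scope="session")
def kernel(network, params):
    return pf.compile_kernel(network, params)


@pytest.fixture(scope="session")
def thresholds(network, params):
    return pf.marker_thresholds(network, params)


@pytest.fixture(scope="session")
def attractors(network, params):
    return pf.reference_attractors(network, params)


@pytest.fixture(scope="session")
def dev_ensemble(network, params):
    """The default wild-type developmental run (100 cells, D=0.05, seed 1)."""
    return pf.simulate_ensemble(100, network, params, master_seed=1)


@pytest.fixture(scope="session")
def small_ensemble(network, params):
    """A cheap 10-cell run for plumbing tests."""
    p = params.with_(n_cells=10, t_end=100.0)
    return pf.simulate_ensemble(10, network, p, master_seed=5, t_end=100.0)
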
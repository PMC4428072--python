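import numpy as np
import pytest

import pefskin as pk
from pefskin.thermal import joule_source_map, solve_transient


@pytest.fixture(scope="session")
def ep_stack():
    return pk.default_stack("electroporated")


@pytest.fixture(scope="session")
def paper_domain(ep_stack):
    """Default-resolution fold domain for the treatment-protocol runs."""
    return pk.build_fold_domain(ep_stack)


@pytest.fixture(scope="session")
def paper_field(paper_domain):
    pot = pk.solve_potential_2d(paper_domain, 500.0)
    return pot, pk.efield_from_potential(pot)


@pytest.fixture(scope="session")
def paper_protocol():
    return pk.PulseProtocol(voltage=500.0, t_p=70e-6, n_pulses=200, freq=3.0)


@pytest.fixture(scope="session")
def paper_thermal(paper_domain, paper_field, paper_protocol):
    """Full 70-s transient run of the treatment protocol."""
    _, emap = paper_field
    q = joule_source_map(emap, paper_domain, paper_protocol)
    bc = pk.ThermalBoundary()
    return solve_transient(paper_domain, q, bc, dt=0.05, t_end=70.0), q, bc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
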
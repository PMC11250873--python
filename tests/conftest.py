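import numpy as np
import pytest

from dwscrash.crp import CRPSpec, fit_crp
from dwscrash.ordinal import fit_fixed
from dwscrash.simulate import generate_scenario, recovery_scenario, scenario_design


@pytest.fixture(scope="session")
def compact_scenario():
    """Small draw from the compact recovery scenario, shared across tests."""
    config = recovery_scenario(n=800, seed=42)
    design, filtered = scenario_design(generate_scenario(config))
    return config, design, filtered


@pytest.fixture(scope="session")
def fixed_fit(compact_scenario):
    _, design, _ = compact_scenario
    return fit_fixed(design)


@pytest.fixture(scope="session")
def crp_fit(compact_scenario):
    config, design, _ = compact_scenario
    spec = CRPSpec(random_columns=config.random_columns, D=60)
    return fit_crp(design, spec, gtol=1e-4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
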
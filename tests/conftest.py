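import numpy as np
import pytest

np.seterr(over="ignore")  # saturating sigmoid far from threshold is benign

from specdcm.behavior import fit_mixture
from specdcm.microcircuit import NetworkModel, build_chain_network
from specdcm.simulate import BehaviorSimSpec, simulate_behavior


@pytest.fixture(scope="session")
def chain_arch():
    return build_chain_network(3)


@pytest.fixture(scope="session")
def chain_model(chain_arch):
    return NetworkModel(chain_arch)


@pytest.fixture(scope="session")
def chain_csd(chain_model):
    return chain_model.predicted_csd()


@pytest.fixture(scope="session")
def std_spec():
    """Reference behavioral ground truth used across tests."""
    return BehaviorSimSpec(n_trials=2000, kappa=8.0, gamma=0.10, beta=0.15, seed=11)


@pytest.fixture(scope="session")
def std_reports(std_spec):
    return simulate_behavior(std_spec)


@pytest.fixture(scope="session")
def std_fit(std_reports):
    return fit_mixture(std_reports, random_state=0)
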
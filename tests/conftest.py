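import numpy as np
import pytest

from ingnet.neuron import FIG3_NEURON
from ingnet.prc import compute_prc


@pytest.fixture(scope="session")
def fig3_neuron():
    return FIG3_NEURON


@pytest.fixture(scope="session")
def hyper_prc():
    """Hyperpolarizing PRC of the reference neuron at the theta midpoint."""
    return compute_prc(FIG3_NEURON, 7.0, E_syn=-75.0, dt=0.01)


@pytest.fixture(scope="session")
def shunt_prc():
    return compute_prc(FIG3_NEURON, 7.0, E_syn=-55.0, dt=0.01)


@pytest.fixture(scope="session")
def candidate_pool():
    from ingnet.population import sample_candidates
    return sample_candidates(seed=0)


@pytest.fixture(scope="session")
def standard_population():
    """The screened 100-neuron heterogeneous population (seed 0)."""
    from ingnet.experiments import build_heterogeneous_population
    return build_heterogeneous_population(0, 100)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
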
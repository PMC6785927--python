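import pytest

from pareto_metab import GridSpec, epsilon_constraint_sample, make_fixture
from pareto_metab.cellline import fit_cell_line
from pareto_metab.synthetic import make_synthetic_panel


@pytest.fixture(scope="session")
def chain_net():
    return make_fixture("chain-net")


@pytest.fixture(scope="session")
def y_net():
    return make_fixture("Y-net")


@pytest.fixture(scope="session")
def parallel_net():
    return make_fixture("parallel-net")


@pytest.fixture(scope="session")
def ferm_resp_net():
    return make_fixture("ferm-resp-net")


@pytest.fixture(scope="session")
def y_front(y_net):
    return epsilon_constraint_sample(y_net, grid=GridSpec(levels=8))


@pytest.fixture(scope="session")
def parallel_front(parallel_net):
    return epsilon_constraint_sample(parallel_net, grid=GridSpec(levels=6))


@pytest.fixture(scope="session")
def fr_front(ferm_resp_net):
    return epsilon_constraint_sample(ferm_resp_net, grid=GridSpec(levels=10))


@pytest.fixture(scope="session")
def fr_panel(ferm_resp_net, fr_front):
    return make_synthetic_panel(ferm_resp_net, fr_front, 30, noise_sigma=0.05, seed=2)


@pytest.fixture(scope="session")
def fr_models(ferm_resp_net, fr_front, fr_panel):
    return [
        fit_cell_line(ferm_resp_net, fr_front, p, top_fraction=0.05)
        for p in fr_panel.profiles
    ]
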
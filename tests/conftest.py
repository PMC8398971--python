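import numpy as np
import pytest

from frdex.pipeline import build_frdex
from frdex.synthetic import GeneratorSpec, make_ideal_stack, make_pair_dataset


@pytest.fixture(scope="session")
def spec():
    return GeneratorSpec()


@pytest.fixture(scope="session")
def stack(spec):
    """Default three-tetrad, 12-guanine idealized stack."""
    return make_ideal_stack(spec)


@pytest.fixture(scope="session")
def pair_data(spec, stack):
    sites, graph, _ = stack
    return make_pair_dataset(sites, graph, spec, n_ct_per_direction=2)


@pytest.fixture(scope="session")
def frdex_ham(spec, stack, pair_data):
    sites, graph, _ = stack
    return build_frdex(sites, graph, pair_data, n_ct_per_direction=2)


@pytest.fixture(scope="session")
def frdex_ham_stacked_ct(spec, stack, pair_data):
    """24 LE + 32 CT basis (CT states only on the 8 stacked pairs)."""
    sites, graph, _ = stack
    return build_frdex(sites, graph, pair_data, n_ct_per_direction=2,
                       ct_policy="stacked")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
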
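import numpy as np
import pytest

from tedyn import synthio


@pytest.fixture(scope="session")
def intact_library():
    """Small all-intact consensus library."""
    params = synthio.SimParams(seed=42, n_families=4, status_weights=(1.0, 0.0, 0.0))
    return synthio.gen_library(params)


@pytest.fixture(scope="session")
def one_consensus(intact_library):
    return next(iter(intact_library.values()))


@pytest.fixture(scope="session")
def small_genome():
    """A compact genome build with truth and hits shared across tests."""
    params = synthio.SimParams(seed=7, n_families=8, copies_per_family=6,
                               genome_length=700_000)
    library = synthio.gen_library(params)
    genome, truth, hits = synthio.build_genome(params, library)
    return params, library, genome, truth, hits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
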
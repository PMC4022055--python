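import pytest
from hypothesis import settings

from genonet import brute_force_enumerate, fixture_library, generate_universe

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def _case(name):
    case = fixture_library()[name]
    universe, envs = generate_universe(case.spec)
    return universe, envs


@pytest.fixture(scope="session")
def pentose():
    """Two-route universe (lengths 2 and 3): the fragmentation fixture."""
    return _case("pentose_like")


@pytest.fixture(scope="session")
def pentose_oracle(pentose):
    universe, envs = pentose
    return brute_force_enumerate(universe, envs)


@pytest.fixture(scope="session")
def double_motif():
    """Two independent route pairs: multiplicative fragmentation."""
    return _case("double_motif")


@pytest.fixture(scope="session")
def double_motif_oracle(double_motif):
    universe, envs = double_motif
    return brute_force_enumerate(universe, envs)


@pytest.fixture(scope="session")
def chain():
    """All-essential linear universe: exactly one viable genotype."""
    return _case("all_essential_chain")


@pytest.fixture(scope="session")
def redundant():
    """Universe with duplicated conversions: nothing superessential is forced."""
    return _case("redundant_pairs")


@pytest.fixture(scope="session")
def redundant_oracle(redundant):
    universe, envs = redundant
    return brute_force_enumerate(universe, envs)


@pytest.fixture(scope="session")
def multi_source():
    """Two minimal environments with different sole carbon sources."""
    return _case("multi_source")
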
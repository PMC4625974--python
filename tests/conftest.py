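import pytest

from fluxsum import SolveConfig, make_mixed_acid_fixture, make_two_branch_fixture


@pytest.fixture(scope="session")
def two_branch():
    return make_two_branch_fixture()


@pytest.fixture(scope="session")
def mixed_acid():
    return make_mixed_acid_fixture(with_pdc=False)


@pytest.fixture(scope="session")
def mixed_acid_pdc():
    return make_mixed_acid_fixture(with_pdc=True)


@pytest.fixture(scope="session")
def config():
    return SolveConfig()


@pytest.fixture(scope="session")
def k_grid():
    return tuple(round(0.1 * i, 1) for i in range(11))
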
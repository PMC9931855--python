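import pytest

from consentcodes import fixtures


@pytest.fixture(scope="session")
def request_grid():
    return fixtures.request_grid()


@pytest.fixture(scope="session")
def profile_grid_1_1():
    """All valid profiles with ≤1 secondary and ≤1 requirement companion."""
    return fixtures.enumerate_profile_grid(1, 1)


@pytest.fixture(scope="session")
def bare_primaries():
    return fixtures.enumerate_profile_grid(0, 0)
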
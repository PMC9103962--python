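import pytest
from hypothesis import settings

from fraudrates import PeriodDesign, builtin_fixture, npc_global_test

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def icqrf():
    """The embedded ICQRF record: (sector totals, 9 x 24 rate matrix)."""
    return builtin_fixture()


@pytest.fixture(scope="session")
def fixture_rates(icqrf):
    return icqrf[1]


@pytest.fixture(scope="session")
def design():
    return PeriodDesign(cutoff_year=2004)


@pytest.fixture(scope="session")
def exhaustive_npc(fixture_rates, design):
    """Exhaustive NPC global test on the full record (all C(24,8) splits).

    Session-scoped: the enumeration takes a few seconds and several tests
    read different facets of the same result.
    """
    return npc_global_test(fixture_rates, design)
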
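import pytest
from hypothesis import settings

from gcmeta import bundled_table1, study_effects

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    return bundled_table1()


@pytest.fixture(scope="session")
def effects1(table1):
    """Per-study allele-model effect estimates of the bundled table."""
    return study_effects(table1)
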
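import pytest

from sentinelchd import load_concept_dictionary, load_cohort_spec
from sentinelchd.quality_flags import load_ruleset


@pytest.fixture(scope="session")
def dictionary():
    return load_concept_dictionary()


@pytest.fixture(scope="session")
def ruleset():
    return load_ruleset()


@pytest.fixture(scope="session")
def default_spec():
    return load_cohort_spec()
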
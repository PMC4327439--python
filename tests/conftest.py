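import pytest
from hypothesis import settings

from slapb.synthetic import (
    reference_scenario,
    simulate,
    toy_category_map,
    toy_lexicon,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return toy_lexicon()


@pytest.fixture(scope="session")
def small_scenario():
    """A 3,000-user instance of the reference study conditions: five
    conditions, one planted precursor (relative hazard 4), one news spike."""
    config = reference_scenario(seed=7, n_users=3000)
    log, truth = simulate(config)
    return config, log, truth


@pytest.fixture(scope="session")
def small_category_map(small_scenario):
    config, _, _ = small_scenario
    return toy_category_map(config)
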
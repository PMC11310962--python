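import pytest
from hypothesis import settings

from dairylca import SyntheticScenario, generate_scenario, load_trial_fixtures

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixtures():
    """The three calibrated feeding-trial pairs and their factor table."""
    return load_trial_fixtures()


@pytest.fixture(scope="session")
def scenario():
    """One randomized three-trial scenario with uncertain factors."""
    return generate_scenario(SyntheticScenario(seed=42, gsd_range=(1.05, 1.3)))
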
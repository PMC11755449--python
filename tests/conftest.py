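import pytest

from smartavg import default_parameters, generate_scenarios


@pytest.fixture(scope="session")
def bundle():
    """Base-case parameter bundle."""
    return default_parameters()


@pytest.fixture(scope="session")
def scenarios():
    """Small batch of random scenario bundles for property checks."""
    return generate_scenarios(25, seed=20230)
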
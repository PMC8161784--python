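import pytest

from mdcecon import CostParameters, default_spec, generate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def calibrated_cohort(spec):
    return generate_cohort(spec, seed=7, calibrated=True)


@pytest.fixture
def base_params():
    return CostParameters()
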
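import pytest

from idaburden import (
    EffectModel,
    default_consumption,
    default_parameters,
    default_population,
)


@pytest.fixture(scope="session")
def strata():
    return default_population()


@pytest.fixture(scope="session")
def profile():
    return default_consumption()


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def effect_model():
    return EffectModel()
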
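import pytest

from saltimpact import (
    GeneratorConfig,
    RiskGradient,
    SbpEffectModel,
    generate_population,
)


@pytest.fixture(scope="session")
def default_pop():
    """Synthetic China-like baseline table, 20 strata, seed 1."""
    return generate_population(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def gradient():
    return RiskGradient.default()


@pytest.fixture(scope="session")
def trial_model():
    return SbpEffectModel.default("trial_based")


@pytest.fixture(scope="session")
def population_model():
    return SbpEffectModel.default("population_based")
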
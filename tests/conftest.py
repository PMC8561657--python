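import pytest

from hydrogem import ScenarioConfig, build_default_model

try:  # hypothesis is optional at runtime but standard for the suite
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, derandomize=True,
                              max_examples=30)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def base_model():
    """Base-case core model (ferredoxin hydrogenase, proton module off)."""
    return build_default_model()


@pytest.fixture(scope="session")
def bifurcating_model():
    return build_default_model(ScenarioConfig(hydrogenase_mode="bifurcating"))


@pytest.fixture(scope="session")
def proton_model():
    return build_default_model(ScenarioConfig(proton_module_enabled=True))


@pytest.fixture()
def model(base_model):
    """A fresh mutable copy of the base model."""
    return base_model.copy()
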
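import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from springtracer import field_data
from springtracer.synthetic_experiment import SyntheticConfig


@pytest.fixture
def amphitheater_2017():
    return field_data.amphitheater_2017()


@pytest.fixture
def lemonade_creek():
    return field_data.lemonade_creek()


@pytest.fixture
def hot_spring_basin():
    return field_data.hot_spring_basin()


@pytest.fixture
def dic_assay_config():
    """The worked-example DIC assay: triplicate light/dark/killed."""
    return SyntheticConfig()
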
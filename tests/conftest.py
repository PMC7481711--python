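import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ventsplit.params import (DEFAULT_SETTINGS, SplitterConfig, VentilatorSettings,
                              lung_preset)


@pytest.fixture(scope="session")
def default_settings() -> VentilatorSettings:
    """Reference ventilation: PIP 15 / PEEP 5 cmH2O, RR 15, I:E 1:2."""
    return DEFAULT_SETTINGS


@pytest.fixture(scope="session")
def lungs() -> dict:
    return {label: lung_preset(label) for label in "ABCD"}


@pytest.fixture(scope="session")
def standard_splitter() -> SplitterConfig:
    return SplitterConfig(topology="standard")
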
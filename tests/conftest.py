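import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from isgquant import DesignConstraints, design_isgs
from isgquant.presets import PUBLISHED_PRIMER_SETS


@pytest.fixture(scope="session")
def primer_sets():
    return PUBLISHED_PRIMER_SETS


@pytest.fixture(scope="session")
def default_designs(primer_sets):
    """Four 615-bp ISG variants designed once for the whole suite."""
    return design_isgs(primer_sets, DesignConstraints(), seed=1)
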
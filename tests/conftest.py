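import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pampa_skin import default_geometry, table1_fixture
from pampa_skin.classification import classify_summaries


@pytest.fixture(scope="session")
def geometry():
    """The packaged sandwich geometry (300/400 µL, 0.196 cm² effective,
    7 h − 20 min transport window, 100 µM donor)."""
    return default_geometry()


@pytest.fixture()
def table1():
    """The 26-compound reference table, unclassified."""
    return table1_fixture()


@pytest.fixture()
def table1_classified():
    fx = table1_fixture()
    classify_summaries(fx)
    return fx
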
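import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from renalpbpk.io import load_drug, load_population  # noqa: E402


@pytest.fixture(scope="session")
def mild():
    return load_population("mild_cn")


@pytest.fixture(scope="session")
def moderate():
    return load_population("moderate_cn")


@pytest.fixture(scope="session")
def severe():
    return load_population("severe_cn")


@pytest.fixture(scope="session")
def healthy():
    return load_population("healthy_cn")


@pytest.fixture(scope="session")
def ceftazidime():
    return load_drug("ceftazidime")


@pytest.fixture(scope="session")
def all_drugs():
    return [load_drug(n) for n in
            ("ceftazidime", "cefodizime", "vancomycin", "cefuroxime")]
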
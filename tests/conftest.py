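import pytest
from hypothesis import HealthCheck, settings

from phasemet.rules import get_compound

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

PARENT_NAMES = (
    "ADB-BUTINACA",
    "MDMB-4en-PINACA",
    "BZO-HEXOXIZID",
    "BZO-POXIZID",
    "BZO-4en-POXIZID",
    "5F-BZO-POXIZID",
)


@pytest.fixture(scope="session")
def adb():
    return get_compound("ADB-BUTINACA")


@pytest.fixture(scope="session")
def mdmb():
    return get_compound("MDMB-4en-PINACA")


@pytest.fixture(scope="session")
def bzo_poxizid():
    return get_compound("BZO-POXIZID")


@pytest.fixture(scope="session")
def fluoro_poxizid():
    return get_compound("5F-BZO-POXIZID")


@pytest.fixture(scope="session")
def hexoxizid():
    return get_compound("BZO-HEXOXIZID")
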
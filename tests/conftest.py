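import math

import pytest
from hypothesis import settings

from cyclesens.models import build_model
from cyclesens.simulate import find_steady_cycle

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

MU100 = math.log(2.0) / 100.0


@pytest.fixture(scope="session")
def pfeuty():
    return build_model("pfeuty")


@pytest.fixture(scope="session")
def pfeuty_steady(pfeuty):
    """Converged steady cycle of the minimal model: (metrics, birth state)."""
    return find_steady_cycle(pfeuty)


@pytest.fixture(scope="session")
def chen():
    return build_model("chen")


@pytest.fixture(scope="session")
def chen_steady(chen):
    return find_steady_cycle(chen)
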
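import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "fragsim",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fragsim")


@pytest.fixture(scope="session")
def unit_window():
    from fragsim import Window
    return Window()


@pytest.fixture(scope="session")
def planar_window():
    from fragsim import Window
    return Window(topology="planar")
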
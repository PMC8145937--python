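import numpy as np
import pytest

from sorabeq import PROTOCOL_TIMES, StructuralParams, VariabilityParams


@pytest.fixture
def params():
    """Default structural parameters (population point estimates)."""
    return StructuralParams()


@pytest.fixture
def novar():
    """All variance components zero: fully deterministic pipeline."""
    return VariabilityParams.none()


@pytest.fixture
def protocol_times():
    return np.asarray(PROTOCOL_TIMES)
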
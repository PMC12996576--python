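import numpy as np
import pytest

from petinput.core_model import ExperimentConfig, default_mouse_schedule
from petinput.synthetic_data import DEFAULT_FENG


@pytest.fixture
def dense_t():
    """Dense 1 s grid covering the default 45.5 min scan."""
    return np.arange(0.0, 2730.5, 1.0)


@pytest.fixture
def reference_config():
    return ExperimentConfig()


@pytest.fixture
def schedule():
    return default_mouse_schedule()


@pytest.fixture
def feng_reference():
    return DEFAULT_FENG
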
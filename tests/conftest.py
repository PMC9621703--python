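import numpy as np
import pytest

from interbrain import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_config():
    """2 s of dynamics: enough samples for PLV after the 0.5 s edge trims."""
    return SimulationConfig(duration_s=2.0)
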
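import numpy as np
import pytest

from mistrat.scenarios import ScenarioTable


@pytest.fixture(scope="session")
def table():
    """Session-wide scenario table; entries are calibrated lazily and cached."""
    return ScenarioTable(n_calibration=10**6)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
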
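import numpy as np
import pytest

from cuednum import SessionDesign, generate_session


@pytest.fixture
def design():
    return SessionDesign()


@pytest.fixture
def small_trials(design):
    """One deterministic session with the default observers."""
    return generate_session(design, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
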
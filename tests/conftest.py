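import logging

import numpy as np
import pytest

from nirspipe.probe_geometry import build_default_layout
from nirspipe.synthetic_data import make_design

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture(scope="session")
def design():
    """Full-size default block design: 20 trials, 10 s / 15 s, 7.14 Hz."""
    return make_design()


@pytest.fixture(scope="session")
def small_design():
    """Short design for fast GLM/regression tests."""
    return make_design(n_trials=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260905)
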
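import numpy as np
import pytest

from profilefit.profile_model import PiecewiseParams
from profilefit.synthetic import DEFAULT_TIME_GRID


@pytest.fixture
def grid():
    return np.asarray(DEFAULT_TIME_GRID)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def transient_params(grid):
    """A transient-up profile with knots on sampling times."""
    t0 = grid[0]
    return PiecewiseParams(t0, 1.0, 2.0, 2.0, 16.0, 0.3, 2.0, 0.4)
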
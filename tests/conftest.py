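import numpy as np
import pytest

from dton.spline import DEFAULT_TIMEPOINTS, compute_knots


@pytest.fixture(scope="session")
def grid():
    """The 12-point sampling grid of the motivating 32-hour time course."""
    return DEFAULT_TIMEPOINTS.copy()


@pytest.fixture(scope="session")
def knots(grid):
    return compute_knots(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
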
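import numpy as np
import pytest

from fdapower import DomainGrid, FunctionalSample


@pytest.fixture
def grid101():
    return DomainGrid()


@pytest.fixture
def point_grid():
    """A single-point domain, where every method reduces to a scalar test."""
    return DomainGrid([0.0])


def make_sample(grid, values, label="g"):
    return FunctionalSample(grid, np.asarray(values, dtype=float), label)


@pytest.fixture
def tiny_point_samples(point_grid):
    """The 4-vs-4 scalar data used for hand-checkable oracles."""
    g1 = make_sample(point_grid, [[1.1], [0.9], [1.0], [1.2]], "g1")
    g2 = make_sample(point_grid, [[0.1], [-0.1], [0.2], [-0.2]], "g2")
    return g1, g2
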
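import numpy as np
import pytest

from ndc.mic import SampleSeries


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def perfect_series():
    """Two fully separated classes: one cut isolates them exactly."""
    return SampleSeries([1, 2, 3, 4, 10, 11, 12, 13], [0, 0, 0, 0, 1, 1, 1, 1])


@pytest.fixture
def flank_series():
    """Class 1 in the middle of class 0's range; only two bins admissible at n=12."""
    return SampleSeries(list(range(1, 13)), [0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0])


def random_series(rng, n=None, with_ties=False):
    """A random valid SampleSeries for oracle/property checks."""
    n = n or int(rng.integers(8, 26))
    x = rng.normal(size=n)
    if with_ties:
        x = np.round(x * 2) / 2
    while True:
        n1 = int(rng.integers(1, n))
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[:n1]] = 1
        if 0 < y.sum() < n:
            return SampleSeries(x, y)
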
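import numpy as np
import pytest

from saddleperm import DesignSpec, SubjectRecord


@pytest.fixture
def three_event_records():
    """Three subjects, times 1 < 2 < 3, all events, two clusters."""
    return [
        SubjectRecord("A", 1, 1.0, 1),
        SubjectRecord("A", 1, 2.0, 1),
        SubjectRecord("B", 2, 3.0, 1),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


def random_centered_scores(rng, n, integer=False):
    if integer:
        c = rng.integers(-5, 6, size=n).astype(float)
    else:
        c = rng.normal(size=n)
    c -= c.mean()
    if np.allclose(c, 0):
        c = np.arange(n, dtype=float)
        c -= c.mean()
    return c


@pytest.fixture
def small_design():
    return DesignSpec((3, 3))
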
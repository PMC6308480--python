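import numpy as np
import pytest

from polyqrs.rpeak import BeatSegment


def make_segment(samples, fs: float = 250.0) -> BeatSegment:
    """Wrap a bare sample array as an R-R section starting at index 0."""
    samples = np.asarray(samples, dtype=float)
    return BeatSegment(0, len(samples) - 1, samples, fs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
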
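import numpy as np
import pytest

from qluss.datasets import load_table1
from qluss.frames_io import SubPleuralROI


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_roi(pixels) -> SubPleuralROI:
    """Wrap a raw array as a sub-pleural ROI (tests bypass frame plumbing)."""
    return SubPleuralROI(np.asarray(pixels, dtype=np.uint8), pleural_row=0, offset=0)


@pytest.fixture()
def roi_factory():
    return make_roi
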
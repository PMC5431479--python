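import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from gliaspat.patterns import PointPattern, rectangle_window
from gliaspat.synthgen import SynthPatternParams, simulate_pattern


@pytest.fixture
def square_mm() -> "PointPattern":
    """CSR pattern at 200/mm² in a 1 mm² square window."""
    return simulate_pattern(
        SynthPatternParams(
            window=rectangle_window(1000, 1000), intensity=200, seed=42
        )
    )


@pytest.fixture
def big_window():
    return rectangle_window(2000, 2000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
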
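import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dygnet import io


@pytest.fixture
def small_expr() -> io.ExpressionMatrix:
    """3 cells x 2 genes raw counts."""
    values = np.array([[0.0, 2.0], [1.0, 4.0], [3.0, 0.0]])
    return io.ExpressionMatrix(values, ["c1", "c2", "c3"], ["gA", "gB"], "raw")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
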
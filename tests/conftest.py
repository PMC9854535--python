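import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mitoboost import synthetic
from mitoboost.features import split_table


@pytest.fixture(scope="session")
def separable_table():
    """Near-separable two-Gaussian table (n=200, 3-sigma shift)."""
    df = synthetic.generate_feature_table(100, dim=5, shift=3.0, seed=11)
    return split_table(df)


@pytest.fixture(scope="session")
def overlapping_table():
    """Overlapping two-Gaussian table (n=200, 1-sigma shift)."""
    df = synthetic.generate_feature_table(100, dim=4, shift=1.0, seed=5)
    return split_table(df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
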
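import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from clrdiff import ConditionDesign, CountTable


@pytest.fixture
def worked_example() -> np.ndarray:
    """The 4-part demonstration composition used throughout the docs."""
    return np.array([10, 35, 50, 500])


@pytest.fixture
def small_table() -> CountTable:
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 200, size=(12, 6))
    counts[0] = 0  # one all-zero feature to exercise the filter
    return CountTable(
        tuple(f"f{i}" for i in range(12)),
        tuple(f"s{j}" for j in range(6)),
        counts,
    )


@pytest.fixture
def small_design(small_table) -> ConditionDesign:
    ids = small_table.sample_ids
    return ConditionDesign({s: ("X" if i < 3 else "Y") for i, s in enumerate(ids)})
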
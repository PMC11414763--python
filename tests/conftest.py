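import io

import numpy as np
import pytest

from mycoassembly import FeatureTable, read_tree


@pytest.fixture
def toy_table():
    """3 samples x 4 ASVs with easily hand-checked counts."""
    return FeatureTable(
        ["S1", "S2", "S3"],
        ["a", "b", "c", "d"],
        np.array([[3, 1, 0, 0], [0, 5, 2, 0], [1, 1, 1, 1]]),
    )


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    return read_tree(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
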
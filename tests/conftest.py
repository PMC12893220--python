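import numpy as np
import pytest

from sidmgf.datatypes import ExpressionMatrix, PathwayCollection


@pytest.fixture
def tiny_expr():
    """3 cells x 4 genes with hand-set integer counts and coordinates."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 4],
            [2, 2, 2, 2],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        counts,
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2", "g3", "g4"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
    )


@pytest.fixture
def tiny_sets():
    return PathwayCollection(
        {"SETA": ["g1", "g3"], "SETB": ["g2", "g4"]},
        {"SETA": "a", "SETB": "b"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
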
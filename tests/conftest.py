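import numpy as np
import pytest

from pseudomst import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """10 genes x 6 cells of positive random expression."""
    vals = rng.uniform(0.5, 8.0, size=(10, 6))
    return ExpressionMatrix(
        values=vals,
        gene_ids=[f"g{i}" for i in range(10)],
        cell_ids=[f"c{j}" for j in range(6)],
    )


@pytest.fixture
def labeled_matrix(rng):
    """20 cells at 4 time points (5 per point), 30 genes."""
    vals = rng.uniform(0.0, 5.0, size=(30, 20))
    return ExpressionMatrix(
        values=vals,
        gene_ids=[f"g{i}" for i in range(30)],
        cell_ids=[f"c{j}" for j in range(20)],
        collection_time=np.repeat([1, 2, 3, 4], 5),
    )
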
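import numpy as np
import pytest

import progclust as pc
from progclust.abundant import SimilarityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """A 5x4 random integer count matrix."""
    vals = rng.integers(0, 20, size=(5, 4))
    return pc.ExpressionMatrix(
        vals, [f"g{i}" for i in range(5)], [f"c{j}" for j in range(4)]
    )


@pytest.fixture
def toy_similarity():
    """4 cells forming two natural pairs: within-pair 0.9, across 0.1."""
    S = np.full((4, 4), 0.1)
    S[0, 1] = S[1, 0] = 0.9
    S[2, 3] = S[3, 2] = 0.9
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, ["a", "b", "c", "d"])


def make_matrix(values, prefix_g="g", prefix_c="c", **kw):
    values = np.asarray(values)
    return pc.ExpressionMatrix(
        values,
        [f"{prefix_g}{i}" for i in range(values.shape[0])],
        [f"{prefix_c}{j}" for j in range(values.shape[1])],
        **kw,
    )
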
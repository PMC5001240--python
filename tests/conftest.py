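import numpy as np
import pandas as pd
import pytest

from cbdn import canonical_tree, population_correlation
from cbdn.influence import influence_matrix_from_correlation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ten_tree():
    """Canonical 10-node benchmark tree at rho = 0.8, no noise."""
    return canonical_tree(10, covariance=0.8)


@pytest.fixture
def ten_pop_corr(ten_tree):
    """Population correlation matrix of the 10-node tree."""
    return population_correlation(ten_tree)


@pytest.fixture
def ten_pop_influence(ten_pop_corr):
    """Population influence matrix of the 10-node tree."""
    return influence_matrix_from_correlation(ten_pop_corr)


@pytest.fixture
def small_expr(rng):
    """Random 30-sample, 6-gene expression frame with correlated columns."""
    base = rng.standard_normal((30, 3))
    extra = 0.6 * base[:, [0, 1, 2]] + 0.8 * rng.standard_normal((30, 3))
    data = np.hstack([base, extra])
    return pd.DataFrame(data, columns=[f"G{i + 1}" for i in range(6)])
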
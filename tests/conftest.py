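import numpy as np
import pytest

from uff.entropy_core import ExpressionMatrix
from uff.synthetic_fixtures import SyntheticSpec, generate_planted_matrix
from uff.uff_exact import rank_features_exact


def random_matrix(rng, m, n, loc=0.0, scale=1.0):
    values = rng.normal(loc, scale, size=(m, n))
    return ExpressionMatrix(
        values,
        [f"f{i}" for i in range(m)],
        [f"s{j}" for j in range(n)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_planted():
    """Default planted matrix + truth (seed 1), shared across tests."""
    return generate_planted_matrix(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def default_exact_table(default_planted):
    matrix, _ = default_planted
    return rank_features_exact(matrix)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted matrix for cheap cross-module tests."""
    spec = SyntheticSpec(
        M=300, N=30, n_informative=30, n_pc1_noise=30, seed=7
    )
    return generate_planted_matrix(spec)
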
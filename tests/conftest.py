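import numpy as np
import pytest

from mrbounds import MarginalTable, ResponseDistribution
from mrbounds.experiments import random_feasible_marginals


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def feasible_tables():
    """300 random three-level marginal tables passing the IV inequalities."""
    tables, _ = random_feasible_marginals(300, seed=11)
    return tables


def random_response_distribution(rng, n_levels=3) -> ResponseDistribution:
    """A random latent response-type law, hence an IV-consistent joint."""
    type_marg = rng.dirichlet(np.ones(4))
    split = rng.uniform(size=(4, n_levels))  # P(X=1 | type, z)
    weights = np.empty((2, 2, 2, n_levels))
    for r, (y0, y1) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        weights[y0, y1, 1] = type_marg[r] * split[r]
        weights[y0, y1, 0] = type_marg[r] * (1.0 - split[r])
    return ResponseDistribution(weights=weights)


@pytest.fixture
def random_joints(rng):
    """60 joints generated from random latent response-type laws."""
    return [random_response_distribution(rng).joint_table() for _ in range(60)]


@pytest.fixture
def null_table():
    return MarginalTable(p_x=(0.5, 0.5, 0.5), p_y=(0.5, 0.5, 0.5))
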
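import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grncomplete import (
    ExpressionMatrix,
    PerturbationConfig,
    enumerate_solutions,
    perturb,
    three_gene_example,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_system():
    """3-gene worked exemplar: x1 = x1²−2, x2 = x2²−6, x3 = x1·x2−1."""
    return three_gene_example()


@pytest.fixture(scope="session")
def toy_solutions(toy_system):
    return enumerate_solutions(toy_system)


@pytest.fixture(scope="session")
def toy_exact_expr(toy_solutions):
    """The four exact solutions as a 3 × 4 expression matrix (no noise)."""
    return ExpressionMatrix(toy_solutions.values.T, toy_solutions.genes)


@pytest.fixture(scope="session")
def toy_noisy_expr(toy_solutions):
    """Exact solutions plus 400 uniform(±0.5) replicates each (m = 1604)."""
    return perturb(toy_solutions, PerturbationConfig(seed=20140326))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
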
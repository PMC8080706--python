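import numpy as np
import pytest

from ragnmf import CohortSpec, MutationMatrix, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """Seeded random 5x8 binary mutation matrix."""
    values = (rng.random((5, 8)) < 0.4).astype(int)
    values[0, 0] = 1  # guarantee no all-zero gene for stability of tests
    return MutationMatrix(
        genes=[f"G{j}" for j in range(8)],
        samples=[f"S{i}" for i in range(5)],
        values=values,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small simulated cohort shared by pipeline-level tests."""
    spec = CohortSpec(
        n_samples=60,
        n_genes=150,
        k_subgroups=3,
        drivers_per_subgroup=5,
        seed=7,
    )
    return simulate_cohort(spec)
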
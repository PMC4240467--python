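import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import commlda

# the scaled gradient study design used across the suite:
# 200 units x 100 species x 100 individuals/unit, 3 communities,
# 9:1 block contrast, one fixed seed
DESIGN_SEED = 2014
FIT_SEED = 1


def match_to_truth(phi_est: np.ndarray, phi_true: np.ndarray) -> np.ndarray:
    """Permutation aligning estimated communities to the true ones
    (minimum total L1 distance between species profiles)."""
    cost = np.abs(phi_est[:, None, :] - phi_true[None, :, :]).sum(axis=2)
    row, col = linear_sum_assignment(cost)
    perm = np.empty(phi_true.shape[0], dtype=int)
    perm[col] = row
    return perm


@pytest.fixture(scope="session")
def scaled_truth() -> commlda.SyntheticTruth:
    return commlda.make_gradient_dataset(
        n_units=200, n_species=100, n_communities=3,
        individuals_per_unit=100, contrast=9.0, seed=DESIGN_SEED,
    )


@pytest.fixture(scope="session")
def scaled_fit(scaled_truth):
    """Complete-data fit at the true number of communities."""
    return commlda.run_gibbs(
        scaled_truth.data, commlda.ModelSpec(3),
        n_iter=2000, burnin=1000, thin=10, seed=FIT_SEED,
    )


@pytest.fixture(scope="session")
def masked_truth(scaled_truth) -> commlda.AbundanceMatrix:
    """Half the units missing half the species, chosen at random."""
    return commlda.apply_missingness(scaled_truth.data, 0.5, 0.5, seed=DESIGN_SEED)


@pytest.fixture(scope="session")
def masked_fit(masked_truth):
    return commlda.gibbs_with_missing(
        masked_truth, commlda.ModelSpec(3),
        n_iter=2000, burnin=1000, thin=10, seed=FIT_SEED,
    )


@pytest.fixture(scope="session")
def small_truth() -> commlda.SyntheticTruth:
    """A cheaper design for tests that need several fits."""
    return commlda.make_gradient_dataset(
        n_units=60, n_species=30, n_communities=3,
        individuals_per_unit=100, contrast=9.0, seed=DESIGN_SEED,
    )
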
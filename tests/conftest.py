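import numpy as np
import pytest

from popstrat import SimulationParams, make_cohort


@pytest.fixture
def small_params():
    """Fast, fully-specified parameter set for unit tests."""
    return SimulationParams(
        n_individuals=300, n_snps=200, causal_fraction=0.1, seed=42
    )


@pytest.fixture
def small_cohort(small_params):
    return make_cohort(small_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_group_genotypes(rng):
    """Two cleanly separated populations: high vs low frequencies at all SNPs."""
    n_half, L = 60, 150
    p = np.r_[np.full(L // 2, 0.9), np.full(L - L // 2, 0.8)]
    q = np.r_[np.full(L // 2, 0.1), np.full(L - L // 2, 0.2)]
    X = np.vstack(
        [
            (rng.random((n_half, L)) < p).astype(np.int8),
            (rng.random((n_half, L)) < q).astype(np.int8),
        ]
    )
    groups = np.r_[np.zeros(n_half), np.ones(n_half)]
    return X, groups
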
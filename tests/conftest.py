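import numpy as np
import pytest

from strmix import GenotypeMatrix, SimConfig, simulate_dataset


@pytest.fixture
def tiny_matrix():
    """2 individuals x 2 loci with one missing call."""
    calls = np.array(
        [
            [[100, 104], [-9, -9]],
            [[100, 100], [200, 204]],
        ]
    )
    return GenotypeMatrix(["ind1", "ind2"], ["locA", "locB"], calls)


@pytest.fixture(scope="session")
def two_pool_dataset():
    """30 + 30 individuals from two diverged pools, 12 loci, no missing."""
    cfg = SimConfig(
        n_forest_locales=1,
        n_savanna_locales=1,
        n_mixed_locales=0,
        individuals_per_locale=30,
        divergence_F=0.3,
        missing_rate=0.0,
        seed=3,
    )
    return simulate_dataset(cfg)


def random_matrix(rng, n=8, L=4, missing_rate=0.1, max_code=12):
    """Small random GenotypeMatrix for round-trip property tests."""
    calls = rng.integers(1, max_code + 1, size=(n, L, 2))
    miss = rng.random((n, L)) < missing_rate
    calls[miss] = -9
    ids = [f"i{k}" for k in range(n)]
    loci = [f"L{j}" for j in range(L)]
    return GenotypeMatrix(ids, loci, calls)
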
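import numpy as np
import pytest

from mmpen import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Modest simulated dataset shared across tests (600 x 150, 3 causal)."""
    cfg = SimConfig(n_samples=600, n_snps=150, n_chromosomes=2,
                    enriched_fraction=0.04, causal_param=0.5, seed=11)
    g, y, truth = simulate_dataset(cfg)
    return g, y, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_regression(rng, n_samples, n_snps, sigma=1.0):
    """Plain random linear system for numerical checks."""
    X = rng.standard_normal((n_samples, n_snps))
    beta = rng.standard_normal(n_snps)
    y = X @ beta + sigma * rng.standard_normal(n_samples)
    return X, y, beta
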
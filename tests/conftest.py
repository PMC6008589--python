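import numpy as np
import pytest

from robustblup import (
    KinshipMatrix,
    ModelData,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_K(rng):
    """Well-conditioned 10x10 kinship from random cross-products."""
    X = rng.normal(size=(10, 40))
    K = X @ X.T / 40 + 0.2 * np.eye(10)
    return KinshipMatrix(labels=[f"s{i}" for i in range(10)], values=K)


@pytest.fixture(scope="session")
def clean_sim():
    """n=100 Gaussian-residual dataset at the generator defaults (h2=0.3)."""
    return simulate_dataset(SimulationConfig(n_individuals=100, seed=42))


@pytest.fixture(scope="session")
def clean_model(clean_sim):
    y = clean_sim.y - clean_sim.y.mean()
    return ModelData(y=y, K=clean_sim.K)


@pytest.fixture(scope="session")
def contaminated_sim():
    """n=100 dataset with 10% of records shifted by 5 residual SDs."""
    return simulate_dataset(SimulationConfig(
        n_individuals=100, seed=7,
        contamination_fraction=0.1, contamination_shift=5.0,
    ))
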
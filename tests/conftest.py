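import numpy as np
import pytest

from longdina import (
    ItemParameters,
    QMatrixSet,
    SimulationConfig,
    StructuralParameters,
    build_anchor_design,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """One small Study-1 condition-2 replication (N=50, I=20, K=4, T=3)."""
    cfg = SimulationConfig(n_persons=50, n_items=20, seed=42,
                           design=build_anchor_design(1, 2, 20))
    return simulate_dataset(cfg)


@pytest.fixture
def toy_single():
    """K=1, T=1 toy: 4 items all requiring the single attribute."""
    q = np.ones((4, 1, 1), dtype=np.int8)
    qmat = QMatrixSet(q)
    items = ItemParameters(np.full((4, 1), -2.197), np.full((4, 1), 4.394))
    struct = StructuralParameters(beta=[1.0], delta=[0.0], mu=[0.0], sigma_mat=[[1.0]])
    return qmat, items, struct
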
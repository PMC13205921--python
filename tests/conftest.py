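import numpy as np
import pandas as pd
import pytest

from hybridexpr.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(n_hybrids=5, n_snps=60, n_genes=120, seed=101)
    return cfg, simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
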
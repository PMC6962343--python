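import numpy as np
import pytest

from advdta.pipeline import PipelineConfig
from advdta.synthetic import SyntheticConfig, simulate_universe


@pytest.fixture(scope="session")
def tiny_universe():
    """Small labeled + unlabeled universe for fast end-to-end tests."""
    cfg = SyntheticConfig(n_drugs=40, n_proteins=15,
                          protein_len_range=(30, 50), smiles_len_range=(10, 20),
                          n_unlabeled_proteins=60, n_unlabeled_drugs=60, seed=123)
    return simulate_universe(cfg)


@pytest.fixture(scope="session")
def fast_cfg():
    """Pipeline config shrunk for unit-test speed (architecture unchanged)."""
    return PipelineConfig(protein_max_len=60, smiles_max_len=24,
                          gan_noise_dim=16, gan_hidden_dims=(32, 32, 32),
                          disc_hidden_dim=64, feature_dim=32,
                          gan_epochs=6, gan_batch_size=32,
                          reg_epochs=8, reg_batch_size=64, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
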
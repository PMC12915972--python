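import numpy as np
import pytest

from mdfuse import SyntheticSpec, TrainConfig, generate_bundle, sample_negatives


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small-dimension config for fast mechanics tests."""
    return TrainConfig(dm=16, dr=16, n_heads=2, nuc_embed_dim=8,
                       cnn_channels=8, head_hidden=16, epochs=5,
                       plm_m_dim=32, plm_r_dim=24, seed=3)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_mirnas=20, n_drugs=8, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate_bundle(small_spec)


@pytest.fixture(scope="session")
def small_pairset(small_bundle):
    return sample_negatives(small_bundle, ratio=1.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
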
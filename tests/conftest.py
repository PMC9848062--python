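import numpy as np
import pytest

from cpifuse.data import generate_synthetic
from cpifuse.model import AffinityModel, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small but structurally complete model configuration."""
    return ModelConfig(
        fp_bits=64, fp_sizes=(32, 16), mpnn_hidden=16, mpnn_depth=2,
        max_len=30, prot_channels=8, prot_kernel=3, prot_blocks=2,
        prot_emb_dim=6, n_tokens=4, embed_dim=8, latent_blocks=1,
        head_hidden=8, seed=1,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return AffinityModel(tiny_config)


@pytest.fixture
def small_dataset():
    """20 compounds x 10 proteins at half density (100 records)."""
    return generate_synthetic(
        n_compounds=20, n_proteins=10, density=0.5, noise_sd=0.3, seed=11,
        length_range=(30, 60),
    )
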
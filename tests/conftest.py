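import numpy as np
import pytest

from dtifuse import ModelConfig, desk_config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Narrow configuration for fast unit tests of the full pipeline."""
    return ModelConfig(
        n_atoms_max=16, drug_grid_width=4,
        d_model=8, drug_fusion_groups=2,
        seq_len_max=16, protein_grid_width=4,
        embed_dim=8, protein_fusion_groups=2,
        ca_reduction=2, d_k=8,
        gated_conv_depth=1,
        head_hidden=(8,), head_dropout=0.0,
        max_epochs=2, batch_size=8, learning_rate=1e-3,
    )


@pytest.fixture
def tiny_batch(tiny_config):
    from dtifuse import featurize_batch
    smiles = ["CCO", "CC(N)C(=O)O", "CNC", "OCCO"]
    seqs = ["ACDHKHMW", "MKWVTFIS", "HKHAC", "GGG"]
    return featurize_batch(tiny_config, smiles, seqs)
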
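import numpy as np
import pytest

from dtafusion import ModelConfig
from dtafusion.datasets import SyntheticConfig, generate_synthetic_benchmark


@pytest.fixture(scope="session")
def small_config() -> ModelConfig:
    """A desk-size architecture: full feature set, tiny widths."""
    return ModelConfig(
        hidden=8,
        heads=2,
        n_gat_layers=2,
        n_gcn_layers=1,
        fusion_width=8,
        dropout=0.0,
        atom_emb_dim=8,
        protein_emb_dim=32,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A small planted-signal benchmark for fast integration tests."""
    return generate_synthetic_benchmark(
        SyntheticConfig(n_drugs=12, n_proteins=5, seq_len=(20, 30), seed=11)
    )


@pytest.fixture(scope="session")
def random_smiles() -> list[str]:
    from dtafusion.datasets import generate_synthetic_molecules

    return generate_synthetic_molecules(SyntheticConfig(seed=42), 500)
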
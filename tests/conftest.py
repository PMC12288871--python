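import numpy as np
import pytest

from graphvar.graph_autoencoder import EncoderConfig, init_model
from graphvar.protein_graphs import build_residue_graph
from graphvar.synthetic_data import CohortConfig, generate_cohort, generate_structure


@pytest.fixture(scope="session")
def helix30():
    return generate_structure(30, seed=42)


@pytest.fixture(scope="session")
def residue_graph30(helix30):
    return build_residue_graph(helix30)


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained residue-scope encoder, embedding dim 8, seeded init."""
    return init_model(EncoderConfig(scope="residue", input_dim=25, embedding_dim=8, n_layers=2), seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(
        CohortConfig(n_genes=10, variants_per_gene=4, n_families=4, residues_per_protein=12, seed=5)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
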
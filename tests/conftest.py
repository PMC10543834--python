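import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smiles_library():
    from dtagnn.data import smiles_template_library

    return smiles_template_library()


@pytest.fixture(scope="session")
def random_graphs(smiles_library):
    """Molecular graphs for 100 valid SMILES drawn from the template library."""
    from dtagnn.molgraph import smiles_to_graph

    rng = np.random.default_rng(7)
    picks = rng.choice(len(smiles_library), size=100, replace=True)
    return [smiles_to_graph(smiles_library[i]) for i in picks]


@pytest.fixture(scope="session")
def tiny_records():
    """32 noiseless synthetic pairs (shared across training tests)."""
    from dtagnn.data import SyntheticSpec, generate_synthetic_dataset

    spec = SyntheticSpec(n_drugs=16, n_proteins=8, n_pairs=32, noise_sd=0.0, seed=5)
    return generate_synthetic_dataset(spec)
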
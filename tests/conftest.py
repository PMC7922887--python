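import numpy as np
import pytest

from metabocc import SimConfig, generate_dataset, load_bundled_metabolite_db


@pytest.fixture(scope="session")
def metabolite_db():
    records, pathway_db = load_bundled_metabolite_db()
    return records, pathway_db


@pytest.fixture(scope="session")
def planted_dataset():
    """Small study with a clear planted signal and missing values."""
    cfg = SimConfig(
        n_case=9, n_control=10, n_features=300, n_discriminant=6,
        effect_size=2.5, missing_rate=0.1, seed=42,
    )
    table, truth = generate_dataset(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def clean_dataset():
    """No missing values, moderate signal; for exact-recovery oracles."""
    cfg = SimConfig(
        n_case=10, n_control=10, n_features=200, n_discriminant=5,
        effect_size=3.0, missing_rate=0.0, seed=7,
    )
    table, truth = generate_dataset(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
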
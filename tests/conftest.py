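import numpy as np
import pandas as pd
import pytest

from gutage import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-featured synthetic cohort shared across tests."""
    cfg = synthetic.GeneratorConfig(
        n_samples=80,
        n_species=10,
        genes_per_species=(15, 25),
        n_metabolites=15,
        n_age_linked_species=4,
        species_age_slopes=(0.02, -0.02, 0.02, -0.02),
        seed=42,
    )
    return synthetic.generate_cohort(cfg)


@pytest.fixture
def abundance_matrix():
    """A tiny hand-written normalized matrix (3 features x 4 samples)."""
    return pd.DataFrame(
        {
            "s1": [0.5, 0.3, 0.2],
            "s2": [0.1, 0.6, 0.3],
            "s3": [0.25, 0.25, 0.5],
            "s4": [0.4, 0.4, 0.2],
        },
        index=["g1", "g2", "g3"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
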
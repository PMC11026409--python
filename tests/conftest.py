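import numpy as np
import pandas as pd
import pytest

from mycoecon import SyntheticConfig, TraitGroup, generate_trait_matrix


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    return (table - table.mean()) / table.std(ddof=1)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default 3-factor synthetic dataset without missing cells."""
    cfg = SyntheticConfig(seed=42, missing_rate=0.0)
    return generate_trait_matrix(cfg)


@pytest.fixture(scope="session")
def planted_table(planted_dataset):
    return standardize(planted_dataset.trait_table)


@pytest.fixture(scope="session")
def single_factor_dataset():
    """One latent factor; anchor traits lead with |loading| 0.9."""
    groups = (
        TraitGroup("anchor", 2, factor=1, loading=0.9),
        TraitGroup("other", 10, factor=1, loading=0.7),
    )
    cfg = SyntheticConfig(
        n_isolates=28, trait_groups=groups, noise_sd=0.2, missing_rate=0.0, seed=3
    )
    return generate_trait_matrix(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
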
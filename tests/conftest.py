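import numpy as np
import pandas as pd
import pytest

from neurocascade.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_subjects=60,
        n_parcels=40,
        n_timepoints=120,
        n_genes=300,
        n_items=24,
        n_syndromes=4,
        n_snps=24,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
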
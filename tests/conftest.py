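import numpy as np
import pytest

from sagtools.simulate import SimulationConfig, simulate_assembly


@pytest.fixture(scope="session")
def small_world():
    """A small simulated multi-SAG dataset with every contaminant class."""
    config = SimulationConfig(
        seed=11, scaffolds_per_organism=15, n_cross_taxon=4, n_organelle=3,
        n_bacterial=3, n_hgt_genes=4, n_stations=8,
    )
    bundles, ledger = simulate_assembly(config)
    return config, bundles, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
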
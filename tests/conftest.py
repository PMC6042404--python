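import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from methcanyon import SimulationConfig
from methcanyon.sim import simulate_genome, simulate_methylome


SMALL = dict(genome_length=2_000_000, n_canyons=4, n_umrs=10, n_genes=60,
             n_deg=42, seed=1)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_methylome(small_genome, small_config):
    track, truth = simulate_methylome(small_genome, small_config)
    return track, truth


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free variant for exact structural checks."""
    return SimulationConfig(**{**SMALL, "occ_noise": 0.0,
                               "meth_dispersion": 0.0})


@pytest.fixture(scope="session")
def clean_genome(clean_config):
    return simulate_genome(clean_config)
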
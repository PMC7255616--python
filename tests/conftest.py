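import numpy as np
import pytest

from locuskit.simulate import SimulationConfig, simulate_gene, simulate_reads


@pytest.fixture(scope="session")
def small_config():
    """Compact default gene with a light read library (fast tests)."""
    return SimulationConfig(seed=101, n_reads=3000, error_rate=0.001,
                            polya_tail_rate=0.2)


@pytest.fixture(scope="session")
def simulated(small_config):
    genome, truth = simulate_gene(small_config)
    reads = simulate_reads(genome, truth, small_config)
    return genome, truth, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
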
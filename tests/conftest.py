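import numpy as np
import pytest

from ptmap.simulate import SimConfig, planted_genome, run_simulation


@pytest.fixture(scope="session")
def planted():
    """Genome with 21 regularly spaced motif sites and known frequencies
    cycling through the partially-modified range seen in bacterial genomes."""
    fvals = [0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4] * 3
    genome, sites = planted_genome(len(fvals), spacing=800, seed=7)
    return genome, sites, np.array(fvals)


@pytest.fixture(scope="session")
def deep_truth(planted):
    """~600x simulated experiment over the planted genome (shearing on)."""
    genome, sites, fvals = planted
    cfg = SimConfig(n_molecules=500, seed=11)
    return run_simulation(cfg, genome=genome, sites=sites, frequencies=fvals)


@pytest.fixture(scope="session")
def default_truth():
    """Simulation under the default study conditions (random 50-kb genome,
    mixture frequency model, shearing enabled)."""
    return run_simulation(SimConfig(seed=3))
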
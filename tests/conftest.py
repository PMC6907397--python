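import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from paleoscaf.synthetic_data import (
    SimConfig,
    fragment_and_corrupt,
    simulate_cross,
    simulate_proximity_ordering,
    simulate_wgd_genome,
)


@pytest.fixture(scope="session")
def flat_genome():
    """13-chromosome genome without duplications (linkage/reconcile tests)."""
    config = SimConfig(n_chromosomes=13, genes_per_chromosome=20,
                       wgd_events=[], seed=1)
    genome, truth = simulate_wgd_genome(config)
    return genome, truth


@pytest.fixture(scope="session")
def corrupted_assembly(flat_genome):
    """Fragmented assembly with 23 planted chimeras and 3 inversions."""
    genome, _ = flat_genome
    assembly, truth = fragment_and_corrupt(genome, 1500, 23, seed=2)
    po, truth = simulate_proximity_ordering(assembly, truth, 3, seed=3)
    return assembly, po, truth


@pytest.fixture(scope="session")
def cross_110(flat_genome):
    """Pseudo-testcross: 110 progeny, 50 markers per chromosome."""
    genome, _ = flat_genome
    gt, truth = simulate_cross(genome, 110, 50, seed=4)
    return gt, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
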
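import numpy as np
import pytest

from tedyn.simulate import SimConfig, simulate_cohort, simulate_genome_pair


@pytest.fixture(scope="session")
def small_sim():
    """Small genome pair shared across tests: 32 insertions of every fate,
    two assembly-gap regions, noisy cohort."""
    cfg = SimConfig(
        seed=42,
        genome_length=400_000,
        n_conserved=8,
        n_specific_a=8,
        n_specific_b=8,
        n_partial_a_in_b=4,
        n_partial_b_in_a=4,
        n_region_count=2,
        deletion_noise_rate=0.02,
    )
    return simulate_genome_pair(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return simulate_cohort(small_sim, small_sim.truth.config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
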
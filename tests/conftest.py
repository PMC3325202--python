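import dataclasses

import pytest

from targetome.synthetic_data import (
    SimulationConfig,
    generate_genome_and_genes,
    nrl_like_pwm,
    plant_sites_and_simulate_tags,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact study used by fast unit tests (single chromosome)."""
    return SimulationConfig(
        seed=5,
        genome_length=150_000,
        n_chroms=1,
        n_genes=20,
        n_target_genes=8,
        n_bound_only=3,
        n_loci=3,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Genome, genes, truth and coverage for the compact study."""
    genome, genes = generate_genome_and_genes(small_config)
    truth, coverage, genome = plant_sites_and_simulate_tags(
        genome, genes, nrl_like_pwm(), small_config
    )
    return {
        "config": small_config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "coverage": coverage,
    }


@pytest.fixture()
def with_seed():
    def make(config: SimulationConfig, seed: int) -> SimulationConfig:
        return dataclasses.replace(config, seed=seed)

    return make
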
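import pytest

from symbiocensus.synthetic_data import (
    SimulationConfig,
    simulate_depth,
    simulate_genomes,
    simulate_variant_table,
)


@pytest.fixture(scope="session")
def cohort():
    """One synthetic cohort shared across tests (default study conditions)."""
    cfg = SimulationConfig(seed=101)
    genomes, features, truth = simulate_genomes(cfg)
    tracks = simulate_depth(cfg, genomes, features, truth)
    return cfg, genomes, features, truth, tracks


@pytest.fixture(scope="session")
def cohort_variants(cohort):
    cfg, genomes, features, truth, _ = cohort
    table, densities = simulate_variant_table(cfg, genomes, features)
    return table, densities
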
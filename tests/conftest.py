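import numpy as np
import pytest

from phagehost.synthetic import (
    PhageFamilySimConfig,
    PopulationSimConfig,
    SeriesSimConfig,
    simulate_bacterial_population,
    simulate_ddpcr_series,
    simulate_phage_family,
)


@pytest.fixture(scope="session")
def small_population():
    """Four-clade population with clustered diagnostic SNPs (fast, seeded)."""
    return simulate_bacterial_population(
        PopulationSimConfig(seed=11, n_clades=4, strains_per_clade=6))


@pytest.fixture(scope="session")
def small_phage_family():
    """Two genera x two species x two genomes each, 4-kb genomes."""
    return simulate_phage_family(
        PhageFamilySimConfig(seed=7, n_genomes=8, genome_length=4000))


@pytest.fixture(scope="session")
def seasonal_series():
    return simulate_ddpcr_series(
        SeriesSimConfig(seed=5, seasonal_period=20.0, log10_sd=0.1))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
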
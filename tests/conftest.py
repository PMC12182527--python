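import numpy as np
import pytest

from wildqtl import (
    GeneticMap,
    generate_elite_line,
    generate_genetic_map,
    generate_tester,
    generate_wild_population,
)
from wildqtl.synthetic import PopulationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_map() -> GeneticMap:
    """Two chromosomes of 50 cM, 50 evenly spaced markers each."""
    return generate_genetic_map(100, 2, 100.0, "even")


@pytest.fixture(scope="session")
def small_pop():
    """A small but realistic wild population shared across test modules."""
    spec = PopulationSpec(
        n_individuals=80,
        n_markers=400,
        n_chromosomes=4,
        total_map_length=80.0,
        target_heterozygosity=0.14,
        maf_mean=0.105,
        burn_in_generations=40,
        burn_in_size=30,
        seed=11,
    )
    gmap = generate_genetic_map(400, 4, 80.0, "even")
    return generate_wild_population(spec, gmap, "test-pop")


@pytest.fixture(scope="session")
def small_founders(small_pop):
    """Elite line and tester matching the small population's map."""
    elite = generate_elite_line(
        small_pop.gmap, seed=5, allele_freq=small_pop.allele_frequency()
    )
    tester = generate_tester(small_pop.gmap, elite, seed=6)
    return elite, tester
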
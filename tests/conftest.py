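import numpy as np
import pytest
from hypothesis import settings

import chiscan as cs

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def background_200kb() -> str:
    """A fixed order-0, GC-balanced background used across tests."""
    return cs.simulate_genome(200_000, gc=0.5, seed=11).sequence


@pytest.fixture(scope="session")
def planted_species():
    """One synthetic species with GCTGGTGG planted at 0.2/kb, 90%
    leading-strand polarized, plus tiled core genes."""
    L = 500_000
    genome = cs.simulate_genome(
        L, gc=0.5, seed=21, species_id="planted", replicon_id="chr"
    )
    genome, truth = cs.plant_polarized_motifs(
        genome,
        "GCTGGTGG",
        density=0.2,
        ori=1,
        ter=L // 2,
        polarization_level=0.9,
        seed=22,
    )
    core = [genome.sequence[i * 5000 : i * 5000 + 1500] for i in range(100)]
    return genome, truth, core


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
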
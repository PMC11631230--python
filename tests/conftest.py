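import numpy as np
import pytest
from hypothesis import settings

from strainsweep.config import CommunityConfig
from strainsweep.simulate import simulate_genus, simulate_timecourse

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def small_community(seed: int = 0, **overrides) -> CommunityConfig:
    """A scaled-down community for unit tests: same planted structure,
    smaller genomes and read sets."""
    params = dict(
        genome_length_bp=16000,
        # keep the island the same fraction of the genome as at full scale
        island_intervals=[(7500, 8700)],
        n_groups=3,
        genomes_per_group=2,
        reads_per_sample=600,
        n_background_genomes=1,
        seed=seed,
    )
    params.update(overrides)
    return CommunityConfig(**params)


@pytest.fixture(scope="session")
def small_cfg() -> CommunityConfig:
    return small_community(seed=7)


@pytest.fixture(scope="session")
def small_genus(small_cfg):
    return simulate_genus(small_cfg)


@pytest.fixture(scope="session")
def small_timecourse(small_cfg, small_genus):
    genomes, truth = small_genus
    samples = simulate_timecourse(genomes, truth, small_cfg, "amended")
    return genomes, truth, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
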
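import numpy as np
import pytest

from steatoseq.config import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast, reduced-scale study configuration for unit tests."""
    return SimulationConfig(
        seed=7,
        chrom_length=60_000,
        n_genes=30,
        depth=6_000,
        field_size=160,
        droplet_count=(4, 8),
        nucleus_count=(2, 4),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_genome(rng: np.random.Generator, length: int,
                  alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))
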
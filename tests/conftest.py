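import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polycopy import GenomeSpec

settings.register_profile(
    "deterministic", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")


@pytest.fixture
def small_genome() -> GenomeSpec:
    """5 Mb single-chromosome genome at the default 1 kb bin grid."""
    return GenomeSpec(chroms=(("chr2L", 5_000_000),), bin_width=1000)


@pytest.fixture
def two_chrom_genome() -> GenomeSpec:
    return GenomeSpec(chroms=(("chr2L", 2_000_000), ("chr3R", 1_500_000)), bin_width=1000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
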
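import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from neopam.genome_io import ReferenceGenome


def make_random_genome(seed: int, length: int = 10_000, gc: float = 0.41,
                       name: str = "chr1") -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return ReferenceGenome({name: seq})


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_genome():
    return make_random_genome(seed=42, length=10_000)
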
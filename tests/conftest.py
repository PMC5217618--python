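import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnvcat.core import Genome, GenomicInterval, Measurement, Track

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20170106)


@pytest.fixture
def small_genome():
    return Genome((("chr1", 2_000), ("chr2", 1_500)))


def random_track(rng, name="t", n=50, chroms=("chr1", "chr2"), coord_max=2_000, max_len=60):
    """Random sorted track with possibly overlapping, variable-length probes."""
    ms = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, coord_max - 1))
        end = start + int(rng.integers(1, max_len + 1))
        ms.append(Measurement(GenomicInterval(chrom, start, end), float(rng.normal())))
    return Track.build(name, ms)


def random_interval(rng, chroms=("chr1", "chr2"), coord_max=2_000, max_len=120):
    chrom = chroms[rng.integers(len(chroms))]
    start = int(rng.integers(0, coord_max - 1))
    return GenomicInterval(chrom, start, start + int(rng.integers(1, max_len + 1)))
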
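import numpy as np
import pytest

from cgimeth.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=500):
    """Small random intervals for brute-force comparisons."""
    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(1, 30))
        out.append(GenomicInterval(chrom, start, end))
    return out
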
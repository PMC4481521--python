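import numpy as np
import pytest

from hotregions.intervals import GenomeLayout, Interval, RegionSet


@pytest.fixture
def toy_genome():
    return GenomeLayout((("chr1", 1_000_000), ("chr2", 1_000_000)))


@pytest.fixture
def hot_2pct_genome():
    """A 3 x 10 Mb genome with a fixed 60 x 10 kb HOT set (2% coverage)."""
    genome = GenomeLayout(tuple((f"chr{i+1}", 10_000_000) for i in range(3)))
    rng = np.random.default_rng(12345)
    ivs = []
    for _ in range(60):
        chrom = genome.names[int(rng.integers(0, 3))]
        s = int(rng.integers(0, 10_000_000 - 10_000))
        ivs.append(Interval(chrom, s, s + 10_000))
    return genome, RegionSet(ivs, label="HOT")
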
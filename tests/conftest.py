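import numpy as np
import pytest

from peakcoloc.intervals import GenomeLayout, GenomicInterval, IntervalSet


@pytest.fixture
def toy_layout():
    return GenomeLayout({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture
def big_layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 1_000_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(layout, *triples, **kwargs):
    return IntervalSet(
        [GenomicInterval(c, s, e, **kwargs) for c, s, e in triples], layout
    )


@pytest.fixture
def mk():
    return make_set
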
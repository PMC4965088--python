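import numpy as np
import pytest

from polydomain.core_io import CoverageTrack, GenomicInterval
from polydomain.peaks import Peak


@pytest.fixture
def rng():
    return np.random.default_rng(20160701)


def make_track(values, bin_size=10, chrom="chr2R"):
    return CoverageTrack(chrom=chrom, bin_size=bin_size,
                         values=np.asarray(values, dtype=float))


def make_peak(chrom="chr2R", start=0, end=100, summit=None, height=100.0):
    if summit is None:
        summit = (start + end) // 2
    return Peak(interval=GenomicInterval(chrom, start, end),
                summit=summit, height=height)
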
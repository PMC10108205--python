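import numpy as np
import pytest

from moranselect.sync_io import LocusCounts


def make_counts(counts, coverage, generations, chrom="chr", pos=1) -> LocusCounts:
    return LocusCounts(
        chrom=chrom,
        pos=pos,
        counts=np.atleast_2d(np.asarray(counts)),
        coverage=np.atleast_2d(np.asarray(coverage)),
        generations=np.asarray(generations, dtype=float),
    )


@pytest.fixture
def constant_counts():
    """A locus whose observed frequency never moves (0.3 everywhere)."""
    c = np.full((3, 4), 3)
    C = np.full((3, 4), 10)
    return make_counts(c, C, [0.0, 5.0, 10.0, 15.0])
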
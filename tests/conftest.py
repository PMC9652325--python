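import numpy as np
import pytest

from abcompare.genome import BinSet, GenomeBins


@pytest.fixture
def bins3() -> GenomeBins:
    """Three 100 kb bins on one chromosome."""
    starts = np.array([0, 100_000, 200_000])
    return GenomeBins("chr1", starts, starts + 100_000, 100_000)


@pytest.fixture
def binset3(bins3) -> BinSet:
    return BinSet({"chr1": bins3}, None)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
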
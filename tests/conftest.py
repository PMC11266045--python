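import numpy as np
import pytest

from pspi.seqio import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, length, start_m=False):
    aa = np.array(list(AMINO_ACIDS))
    seq = "".join(aa[rng.integers(20, size=length)])
    if start_m:
        seq = "M" + seq[1:]
    return seq


@pytest.fixture
def random_peptides(rng):
    def make(n, min_len=5, max_len=30):
        return [
            random_peptide(rng, int(rng.integers(min_len, max_len + 1)))
            for _ in range(n)
        ]

    return make
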
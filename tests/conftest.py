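import numpy as np
import pytest

from neosexqc.alignio import placements_from_arrays
from neosexqc.synthetic import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_lengths():
    return {"s1": 200_000, "s2": 150_000}


def random_placements(rng, lengths, n, read_len=100, mapq=60):
    names = list(lengths)
    ref = rng.integers(0, len(names), n).astype(np.int32)
    len_arr = np.array([lengths[k] for k in names])
    start = np.floor(rng.random(n) * (len_arr[ref] - read_len)).astype(np.int64)
    return placements_from_arrays(lengths, ref, start, start + read_len, mapq=mapq)


@pytest.fixture
def make_placements(rng, small_lengths):
    def _make(n=500, read_len=100):
        return random_placements(rng, small_lengths, n, read_len)

    return _make


@pytest.fixture
def tiny_sequence(rng):
    return random_sequence(rng, 10_000)
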
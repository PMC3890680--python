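import numpy as np
import pytest

from coibarcode.distances import DistanceMatrix
from coibarcode.seqio import Alignment, SequenceRecord


@pytest.fixture
def tiny_alignment():
    return Alignment(
        [
            SequenceRecord("a", "ACGT"),
            SequenceRecord("b", "ACGA"),
            SequenceRecord("c", "ACGT"),
        ]
    )


def matrix_from_pairs(names, pairs):
    """Build a DistanceMatrix from {(i, j): d} over name strings."""
    n = len(names)
    d = np.zeros((n, n))
    idx = {name: k for k, name in enumerate(names)}
    for (a, b), v in pairs.items():
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
    return DistanceMatrix(tuple(names), d)


@pytest.fixture
def two_block_matrix():
    """Two tight clusters {a,b}, {c,d} separated by ~18.5%."""
    return matrix_from_pairs(
        ["a", "b", "c", "d"],
        {
            ("a", "b"): 0.006,
            ("c", "d"): 0.002,
            ("a", "c"): 0.185,
            ("a", "d"): 0.185,
            ("b", "c"): 0.185,
            ("b", "d"): 0.185,
        },
    )
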
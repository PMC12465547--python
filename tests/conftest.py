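import numpy as np
import pytest

from mtdel import build_seed_index, synthetic_reference
from mtdel.io import ReferenceGenome


@pytest.fixture(scope="session")
def ref16k():
    """The default synthetic 16.3 kb circular mitochondrial-like reference."""
    return synthetic_reference()


@pytest.fixture(scope="session")
def small_ref():
    """A 2 kb circular reference for oracle-scale alignment tests."""
    return synthetic_reference(length=2000, seed=7, name="toy")


@pytest.fixture(scope="session")
def small_index(small_ref):
    return build_seed_index(small_ref)


def brute_force_placements(ref_seq: str, read: str, min_anchor: int = 20):
    """All exact placements of a read on a circular reference.

    Returns (singles, splits): ``singles`` is a list of circular start
    positions where the whole read matches; ``splits`` lists
    (cut, start1, start2) such that read[:cut] matches at start1 and
    read[cut:] matches at start2 exactly, with both arms >= min_anchor.
    Exhaustive search — the independent oracle for the seed-and-extend
    aligner on error-free reads.
    """
    L = len(ref_seq)
    doubled = ref_seq + ref_seq
    rl = len(read)

    def occurrences(s):
        out = []
        start = 0
        while True:
            p = doubled.find(s, start)
            if p == -1 or p >= L:
                break
            out.append(p)
            start = p + 1
        return out

    singles = occurrences(read)
    splits = []
    for cut in range(min_anchor, rl - min_anchor + 1):
        left, right = read[:cut], read[cut:]
        for p1 in occurrences(left):
            for p2 in occurrences(right):
                if (p2 - (p1 + cut)) % L > 0:
                    splits.append((cut, p1, p2))
    return singles, splits


@pytest.fixture(scope="session")
def placements_oracle():
    return brute_force_placements
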
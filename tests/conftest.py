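import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ephscan.profilehmm import Alignment, build_profile
from ephscan.seqs import AMINO_ACIDS


@pytest.fixture
def tiny_alignment():
    return Alignment((("s1", "ACDEF"), ("s2", "ACDEF"), ("s3", "ACDEF")))


@pytest.fixture
def tiny_profile(tiny_alignment):
    return build_profile(tiny_alignment, name="tiny")


def random_small_profile(rng, max_match=3):
    """A random valid profile with at most max_match match states."""
    M = int(rng.integers(1, max_match + 1))
    nrow = int(rng.integers(2, 5))
    ncol = M + int(rng.integers(0, 2))
    rows = []
    for r in range(nrow):
        row = "".join(rng.choice(list(AMINO_ACIDS), size=ncol))
        row = "".join(c if rng.random() > 0.2 else "-" for c in row)
        if set(row) == {"-"}:
            row = "A" * ncol
        rows.append((f"s{r}", row))
    try:
        return build_profile(Alignment(tuple(rows)), occupancy_threshold=0.5)
    except Exception:
        return None


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
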
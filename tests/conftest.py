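import math

import numpy as np
import pytest

from dosagecomp import (
    GeneCopy,
    fragments_frame,
    set_lineage_abundances,
    simulate_splitting,
)


@pytest.fixture
def overlap_genes():
    """Three genes on one contig with partial overlaps on mixed strands."""
    return [
        GeneCopy("gA", "famA", "c", 100, 300, "+"),
        GeneCopy("gB", "famB", "c", 250, 400, "+"),
        GeneCopy("gC", "famC", "c", 350, 500, "-"),
    ]


@pytest.fixture
def overlap_fragments():
    """Five fragments over the overlap_genes fixture (one hits nothing)."""
    return fragments_frame(
        ["c"] * 5,
        [120, 240, 380, 360, 600],
        [180, 320, 450, 390, 700],
        ["+", "+", "+", "-", "+"],
    )


@pytest.fixture
def undata_system():
    """A two-lineage system at the 60:40 abundance split."""
    sys = simulate_splitting(40, 2, seed=11)
    return set_lineage_abundances(sys, "T_undata")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_tau_b(x, y):
    """O(n^2) pair enumeration with tie-corrected denominator (test oracle)."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])

    def ties(v):
        _, c = np.unique(v, return_counts=True)
        return sum(t * (t - 1) / 2 for t in c)

    n0 = n * (n - 1) / 2
    return s / math.sqrt((n0 - ties(x)) * (n0 - ties(y)))
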
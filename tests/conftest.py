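import numpy as np
import pytest

from popgenkit.alignment import CodingAnnotation, PopAlignment


@pytest.fixture
def toy3():
    """Three sequences of length 10 with S = 2, k = 4/3."""
    return PopAlignment(
        "toy3", ["a", "b", "c"], ["P1", "P1", "P2"],
        ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT"],
    )


@pytest.fixture
def two_pop_fixed():
    """Two populations each fixed for a distinct haplotype."""
    return PopAlignment(
        "fixed", [f"s{i}" for i in range(8)], ["A"] * 4 + ["B"] * 4,
        ["AAAAAA"] * 4 + ["TTTTTT"] * 4,
    )


def random_alignment(rng, n=None, L=None, pops=("P1", "P2"),
                     with_outgroup=False):
    """Random small alignment for oracle comparisons.  With
    ``with_outgroup`` the true ancestral sequence is attached as outgroup,
    so derived states are known exactly."""
    n = n or int(rng.integers(4, 13))
    L = L or int(rng.integers(10, 61))
    bases = np.array(list("ACGT"))
    anc = rng.integers(4, size=L)
    m = np.tile(anc, (n, 1))
    n_mut = int(rng.integers(1, max(2, L // 3)))
    for _ in range(n_mut):
        c = int(rng.integers(L))
        carriers = rng.random(n) < rng.uniform(0.1, 0.9)
        if carriers.all() or not carriers.any():
            continue
        m[carriers, c] = (anc[c] + 1 + rng.integers(3)) % 4
    seqs = ["".join(bases[row]) for row in m]
    labels = [pops[i % len(pops)] for i in range(n)]
    outgroup = ("anc", "".join(bases[anc])) if with_outgroup else None
    return PopAlignment("rand", [f"s{i}" for i in range(n)], labels, seqs,
                        outgroup=outgroup)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
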
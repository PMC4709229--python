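"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
exact-test p-values are summed in rational arithmetic from the printed
conditional distribution, and hypergeometric tail probabilities are
obtained by exhaustively enumerating draws.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from dgepipe.quantification import CountTable


def ac_pvalue_exact(x: int, y: int, ratio: Fraction) -> Fraction:
    """Two-sided exact-test p-value in rational arithmetic.

    ``ratio`` is N2/N1.  Sums p(i|x) = C(x+i, i) r^i / (1+r)^(x+i+1)
    term by term with :class:`fractions.Fraction`.
    """
    s = sum(
        Fraction(comb(x + i, i)) * ratio**i / (1 + ratio) ** (x + i + 1)
        for i in range(y + 1)
    )
    p = 2 * s if s <= Fraction(1, 2) else 2 * (1 - s)
    return min(Fraction(1), p)


def hypergeom_tail_by_enumeration(N: int, n: int, M: int, m: int) -> Fraction:
    """P(X >= m) by enumerating every n-subset of an N-gene universe.

    The first M genes carry the term; X is the overlap of a draw with them.
    """
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for g in draw if g < M) >= m:
            hits += 1
    return Fraction(hits, total)


def pmf_total_mass(x: int, n1: int, n2: int) -> float:
    """Sum the conditional count distribution with an adaptive cutoff.

    Extends the summation range in 5-sigma blocks until the next term is
    below 1e-17, at which point the truncated geometric tail is far under
    the 1e-9 normalisation tolerance.
    """
    from dgepipe.dge import ac_pmf

    q = n2 / (n1 + n2)
    mean = (x + 1) * q / (1 - q)
    sd = np.sqrt(mean / (1 - q) + 1.0)
    hi = int(mean + 10 * sd) + 50
    total = float(ac_pmf(np.arange(hi), x, n1, n2).sum())
    while ac_pmf(hi, x, n1, n2) > 1e-17:
        new_hi = hi + int(5 * sd) + 50
        total += float(ac_pmf(np.arange(hi, new_hi), x, n1, n2).sum())
        hi = new_hi
    return total


def random_count_table(rng: np.random.Generator, n_genes: int = 50) -> CountTable:
    frame = pd.DataFrame(
        {
            "gene_id": [f"g{i:03d}" for i in range(n_genes)],
            "length": rng.integers(100, 5000, n_genes).astype(np.int64),
            "count_lib1": rng.integers(0, 2000, n_genes).astype(np.int64),
            "count_lib2": rng.integers(0, 2000, n_genes).astype(np.int64),
        }
    )
    return CountTable(frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160115)


@pytest.fixture
def small_table() -> CountTable:
    frame = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "length": np.array([1000, 500, 2000], dtype=np.int64),
            "count_lib1": np.array([10, 1000, 0], dtype=np.int64),
            "count_lib2": np.array([12, 10, 40], dtype=np.int64),
        }
    )
    return CountTable(frame)
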
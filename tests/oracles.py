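"""Independent brute-force oracles used to freeze expected values.

Everything here is exact rational arithmetic or exhaustive enumeration,
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def exact_binomial_cmf(k: int, n: int, f: Fraction) -> Fraction:
    """P(X <= k), X ~ Binomial(n, f), by direct rational summation."""
    f = Fraction(f)
    return sum(
        (comb(n, i) * f**i * (1 - f) ** (n - i) for i in range(k + 1)),
        Fraction(0),
    )


def exact_binomial_upper(k: int, n: int, f: Fraction) -> Fraction:
    """P(X >= k) by summing the complementary lower tail exactly."""
    if k <= 0:
        return Fraction(1)
    return 1 - exact_binomial_cmf(k - 1, n, f)


def exact_hypergeom_tail(a: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= a), X ~ Hypergeometric(N, K, n), exact rational summation."""
    denom = comb(N, n)
    total = sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(a, min(n, K) + 1)
        if n - i <= N - K
    )
    return Fraction(total, denom)


def enumerate_overlap_tail(m: int, n_a: int, n_b: int,
                           population: int) -> Fraction:
    """P(|A ∩ B| >= m) by enumerating all size-n_b subsets against a
    fixed size-n_a subset (overlap law depends only on sizes)."""
    universe = range(population)
    a_set = set(range(n_a))
    hits = total = 0
    for b in itertools.combinations(universe, n_b):
        total += 1
        if len(a_set & set(b)) >= m:
            hits += 1
    return Fraction(hits, total)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_best_score(scores: list[list[float]], sequence: str) -> float:
    """Best window score over both strands by explicit enumeration.

    ``scores`` is W rows of [A, C, G, T]; N scores the row minimum.
    """
    w = len(scores)
    order = "ACGT"

    def window_score(win: str) -> float:
        total = 0.0
        for row, base in zip(scores, win):
            total += min(row) if base not in order else row[order.index(base)]
        return total

    rc = "".join(_COMP[b] for b in reversed(sequence))
    best = float("-inf")
    for strand_seq in (sequence, rc):
        for i in range(len(strand_seq) - w + 1):
            best = max(best, window_score(strand_seq[i:i + w]))
    return best
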
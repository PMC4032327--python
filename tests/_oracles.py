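"""Independent brute-force oracles used by the tests.

These compute expected values by exact integer/rational enumeration,
independently of the library code paths they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

# same tie-admission rule as the implementation contract, as an exact rational
TIE_FACTOR = Fraction(10**7 + 1, 10**7)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by exact rational enumeration of the support."""
    n = a + b + c + d
    r1 = a + b
    k1 = a + c
    if n == 0 or r1 == 0 or r1 == n or k1 == 0 or k1 == n:
        return 1.0
    lo = max(0, k1 - (n - r1))
    hi = min(r1, k1)
    denom = math.comb(n, k1)
    pmfs = [
        Fraction(math.comb(r1, k) * math.comb(n - r1, k1 - k), denom)
        for k in range(lo, hi + 1)
    ]
    p_obs = pmfs[a - lo]
    cut = p_obs * TIE_FACTOR
    return float(sum(p for p in pmfs if p <= cut))


def hypergeom_tail_oracle(k: int, n_bg: int, n_term: int, n_query: int) -> float:
    """P(X >= k) for X ~ Hypergeom(n_bg, n_term, n_query), exact rationals."""
    denom = math.comb(n_bg, n_query)
    hi = min(n_term, n_query)
    total = sum(
        Fraction(math.comb(n_term, x) * math.comb(n_bg - n_term, n_query - x), denom)
        for x in range(k, hi + 1)
    )
    return float(total)


def unique_tables_up_to(n_max: int) -> list[tuple[int, int, int, int]]:
    """All 2x2 tables with total <= n_max, one per symmetry orbit.

    The two-tailed Fisher p is invariant under row swap, column swap and
    transposition, so one representative per orbit suffices for an
    exhaustive comparison.
    """
    seen: set[tuple[int, int, int, int]] = set()
    out: list[tuple[int, int, int, int]] = []
    for n in range(n_max + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    orbit = min(
                        (a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
                        (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
                    )
                    if orbit not in seen:
                        seen.add(orbit)
                        out.append(orbit)
    return out
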
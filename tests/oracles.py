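"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they verify: exact integer
hypergeometric enumeration for Fisher's test and the literal two-point
mass sum for the mandible inertia.
"""

import math


def exhaustive_fisher_ps(r1: int, r2: int, c1: int) -> list[float]:
    """Two-sided Fisher p for every table with margins (r1, r2) × (c1, ·).

    Pure-integer enumeration: each table's probability numerator is
    C(r1, a)·C(r2, c1-a) over the common denominator C(n, c1); the
    two-sided p sums numerators not exceeding the observed one, compared
    exactly in integer arithmetic.
    """
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, a) * math.comb(r2, c1 - a) for a in range(lo, hi + 1)]
    den = math.comb(n, c1)
    return [sum(x for x in nums if x <= obs) / den for obs in nums]


def exhaustive_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for one 2×2 table via exhaustive enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo = max(0, c1 - r2)
    return exhaustive_fisher_ps(r1, r2, c1)[a - lo]


def two_point_mass_inertia(m_a1: float, m_a2: float, l_a: float) -> float:
    """I_A as the literal sum of two point masses at L_COM/2 and (L_COM+L_A)/2."""
    l_com = (0.25 * l_a * m_a2 + 0.75 * l_a * m_a1) / (m_a1 + m_a2)
    return m_a2 * (l_com / 2.0) ** 2 + m_a1 * ((l_com + l_a) / 2.0) ** 2
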
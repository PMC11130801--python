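"""Independent combinatorial oracles used to verify the exact tests.

These deliberately avoid scipy: Fisher's exact p is computed by exhaustive
hypergeometric enumeration with exact rational arithmetic, and the
Mann–Whitney exact p by enumerating every assignment of pooled ranks to the
first sample.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by full enumeration.

    Sums the hypergeometric probabilities (fixed margins) of every table
    whose point probability is at most that of the observed table, using
    exact fractions so inclusion decisions carry no rounding error.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(total)


def mwu_exact_two_sided_enumeration(a, b) -> float:
    """Two-sided exact Mann–Whitney p for tie-free samples, by enumerating
    all C(n_a + n_b, n_a) rank assignments.

    p = P(U <= u_low) + P(U >= u_high), with u_low = min(u, n_a n_b - u) and
    u_high = n_a n_b - u_low; clipped at 1 when the tails meet.
    """
    na, nb = len(a), len(b)
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - na * (na + 1) // 2
    m = na * nb
    u_low = min(u_obs, m - u_obs)
    u_high = m - u_low

    n = na + nb
    count = 0
    for positions in combinations(range(1, n + 1), na):
        u = sum(positions) - na * (na + 1) // 2
        if u <= u_low or u >= u_high:
            count += 1
    return min(1.0, count / comb(n, na))
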
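"""Independent brute-force oracles shared across test modules."""

import math


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Full enumeration of 2x2 tables with the observed margins.

    Sums hypergeometric probabilities of every table whose probability
    does not exceed the observed one (with the conventional small relative
    tolerance for floating-point ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(k: int) -> float:
        return math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)
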
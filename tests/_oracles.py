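"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the binomial tail is
summed by full enumeration with exact rational arithmetic, and the random
+1 interactome overlap distribution is obtained by exhaustive enumeration
over all draw orders (with the truncation step marginalised analytically as
a hypergeometric draw of the final gene's new members).
"""
from __future__ import annotations

from fractions import Fraction
from math import comb


def binomial_upper_tail(k: int, n: int, p_num: int, p_den: int) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p_num/p_den), exact."""
    p = Fraction(p_num, p_den)
    q = 1 - p
    return sum(
        Fraction(comb(n, i)) * p**i * q ** (n - i) for i in range(k, n + 1)
    )


def exact_random_plus_one_overlap_dist(network, pool, target_size, reference):
    """Exact distribution of |random +1 interactome ∩ reference|.

    Enumerates every ordered sequence of distinct universe draws (each next
    draw uniform over the remaining pool).  A draw whose +1 members are all
    already present consumes the draw and contributes nothing.  When a
    draw's new members would reach or exceed the target, the process stops:
    a uniform random subset of the new members fills the remaining room, so
    the added reference overlap is hypergeometric in the new members.

    Returns a dict overlap -> Fraction probability.
    """
    reference = frozenset(reference)
    dist: dict[int, Fraction] = {}

    def recurse(remaining: tuple, acc: frozenset, prob: Fraction):
        n = len(remaining)
        if n == 0:
            raise RuntimeError("pool exhausted before reaching target")
        step = prob / n
        for j in range(n):
            gene = remaining[j]
            rest = remaining[:j] + remaining[j + 1:]
            new = network.plus_one_members(gene) - acc
            room = target_size - len(acc)
            if not new:
                recurse(rest, acc, step)
            elif len(new) < room:
                recurse(rest, acc | new, step)
            else:
                base = len(acc & reference)
                q = len(new & reference)
                total = len(new)
                denom = comb(total, room)
                for h in range(max(0, room - (total - q)), min(q, room) + 1):
                    w = Fraction(comb(q, h) * comb(total - q, room - h), denom)
                    key = base + h
                    dist[key] = dist.get(key, Fraction(0)) + step * w

    recurse(tuple(pool), frozenset(), Fraction(1))
    assert sum(dist.values()) == 1
    return dist
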
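"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: Fisher's exact test by
exact rational enumeration over margin-fixed tables, the rank-sum null by
exhaustive enumeration of group assignments, and the log-rank statistic by
step-by-step risk-set bookkeeping.
"""

import math
from fractions import Fraction
from itertools import combinations


def fisher_two_sided_enumeration(a, b, c, d) -> Fraction:
    """Exact two-sided Fisher p by enumerating all tables with the observed
    margins, using factorial-formula hypergeometric probabilities."""
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return Fraction(1)

    def prob(x):
        # P(X = x) = r1! r2! c1! c2! / (n! x! (r1-x)! (c1-x)! (r2-c1+x)!)
        num = (
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(c2)
        )
        den = (
            math.factorial(n) * math.factorial(x) * math.factorial(r1 - x)
            * math.factorial(c1 - x) * math.factorial(r2 - c1 + x)
        )
        return Fraction(num, den)

    observed = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= observed:
            total += p
    return min(total, Fraction(1))


def rank_sum_two_sided_enumeration(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating every assignment of the
    pooled (tie-free) values to the two groups."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)

    def u_statistic(group1):
        group2 = [v for v in pooled if v not in group1]
        return sum(1 for a in group1 for b in group2 if a > b)

    u_obs = u_statistic(sorted(x))
    n2 = len(y)
    mid = n1 * n2 / 2.0
    dev = abs(u_obs - mid)
    count = 0
    total = 0
    for group1 in combinations(pooled, n1):
        u = u_statistic(list(group1))
        total += 1
        if abs(u - mid) >= dev - 1e-12:
            count += 1
    return count / total


def logrank_enumeration(times_a, events_a, times_b, events_b):
    """Log-rank chi-square by explicit risk-set bookkeeping at each distinct
    event time: statistic = (sum(O - E))^2 / sum(V) with hypergeometric
    variance for ties."""
    records = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in records if e})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in records if tt >= t]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee)
        d_a = sum(1 for tt, ee, g in at_risk if tt == t and ee and g == 0)
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    statistic = o_minus_e**2 / var
    return statistic


def connected_components_closure(nodes, edges):
    """Connected components via brute-force transitive closure (O(n^3))."""
    nodes = sorted(set(nodes))
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    reach = [[i == j for j in range(n)] for i in range(n)]
    for a, b in edges:
        reach[index[a]][index[b]] = True
        reach[index[b]][index[a]] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    seen = set()
    comps = []
    for i, v in enumerate(nodes):
        if v in seen:
            continue
        comp = {nodes[j] for j in range(n) if reach[i][j]}
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
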
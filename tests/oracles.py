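"""Independent brute-force oracles used to check the package's statistics.

Everything here is deliberately written from the defining formulas
(enumeration, explicit rank averaging, direct moment equations with a
bracketing root finder) and stays independent of the implementation path
it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, special


def bh_stepup_oracle(pvals):
    """BH adjusted p straight from the definition: for each i,
    adj_i = min over j with rank(j) >= rank(i) of m * p_j / rank(j),
    capped at 1.  Ranks computed by counting (max rank for ties)."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    ranks = [0] * m
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    # for tied p-values the step-up uses the largest rank of the tie block
    for i in range(m):
        ranks[i] = max(ranks[j] for j in range(m) if p[j] == p[i])
    out = []
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if ranks[j] >= ranks[i]]
        out.append(min(1.0, min(candidates)))
    return out


def hypergeom_upper_oracle(a, b, c, d):
    """One-sided Fisher p by explicit hypergeometric enumeration:
    P(X >= a) with margins (a+b, c+d; a+c, b+d) fixed."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    denom = math.comb(n, col1)
    total = 0.0
    for x in range(a, hi + 1):
        total += math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom
    if a < lo:
        return 1.0
    return total


def average_ranks(values):
    """Average ranks (1-based), ties get the mean of their positions."""
    v = list(map(float, values))
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


def variance_prior_oracle(s2, df):
    """Method-of-moments (d0, s0^2) from the closed-form log-variance
    moment equations, inverting trigamma with a bracketing root finder."""
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, math.exp(emean)
    f = lambda x: float(special.polygamma(1, x)) - evar
    lo, hi = 1e-8, 1e8
    half_d0 = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    d0 = 2.0 * half_d0
    s2_0 = math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
    return d0, s2_0
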
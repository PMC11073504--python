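"""Independent brute-force / textbook-formula oracles used by the tests.

Everything here is deliberately written from the definitions (explicit loops,
closed-form formulas) and shares no code with the package implementations it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Sequence


def brute_force_es(genes: Sequence[str], scores: Sequence[float], members, exponent=1.0):
    """Weighted KS running sum by direct enumeration; returns the signed
    extreme (positive preferred on exact ties)."""
    members = set(members)
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    assert 0 < n_hit < n
    weights = [abs(s) ** exponent for s, h in zip(scores, hits) if h]
    total = sum(weights)
    if total == 0:
        weights = [1.0] * n_hit
        total = float(n_hit)
    miss_step = 1.0 / (n - n_hit)
    running = 0.0
    pos_ext, neg_ext = 0.0, 0.0
    wi = iter(weights)
    for h in hits:
        if h:
            running += next(wi) / total
        else:
            running -= miss_step
        pos_ext = max(pos_ext, running)
        neg_ext = min(neg_ext, running)
    return pos_ext if pos_ext >= -neg_ext - 1e-12 else neg_ext


def welch_t(a: Sequence[float], b: Sequence[float]):
    """Welch's unequal-variance t and Welch-Satterthwaite df."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def anova_f(groups: Sequence[Sequence[float]]):
    """One-way ANOVA F from between/within sums of squares."""
    all_vals = [x for g in groups for x in g]
    n = len(all_vals)
    k = len(groups)
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def pearson_r(x: Sequence[float], y: Sequence[float]):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def ols_slope(x: Sequence[float], y: Sequence[float]):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = sum((a - mx) ** 2 for a in x)
    return num / den


def ks_sup(a: Sequence[float], b: Sequence[float], signed: str = "two_sided"):
    """Supremum ECDF difference by checking every data point."""
    points = sorted(set(a) | set(b))
    d_plus = d_minus = 0.0
    for x in points:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d_plus = max(d_plus, fa - fb)
        d_minus = max(d_minus, fb - fa)
    if signed == "greater":
        return d_plus
    if signed == "less":
        return d_minus
    return max(d_plus, d_minus)


def ranksum_exact_p_greater(a: Sequence[float], b: Sequence[float]):
    """Exact one-sided (a > b) rank-sum p by enumerating group assignments.

    Assumes no ties across the pooled sample; feasible for small groups only.
    """
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "ties not supported"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(rank[v] for v in a)
    na = len(a)
    count = total = 0
    for combo in combinations(range(1, len(pooled) + 1), na):
        total += 1
        if sum(combo) >= obs:
            count += 1
    return count / total
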
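"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (direct
enumeration / naive loops), independent of the library implementations they
check.
"""

from itertools import combinations

import numpy as np


def bruteforce_enrichment_score(metric_sorted, hit, weight_p):
    """Running-sum ES by naive enumeration over every list position."""
    n = len(metric_sorted)
    k = sum(bool(h) for h in hit)
    weights = [abs(m) ** weight_p if h else 0.0 for m, h in zip(metric_sorted, hit)]
    total = sum(weights)
    if total == 0:
        weights = [1.0 if h else 0.0 for h in hit]
        total = float(k)
    best = 0.0
    running = 0.0
    for i in range(n):
        if hit[i]:
            running += weights[i] / total
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def mannwhitney_u(x, y):
    """U statistic of x vs y with half counts at ties (naive double loop)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mannwhitney_exact_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mannwhitney_u(x, y)
    us = []
    idx = range(len(pooled))
    for chosen in combinations(idx, n1):
        chosen_set = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen_set]
        us.append(mannwhitney_u(xs, ys))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def logrank_oracle(times, events, group1_mask):
    """Two-group log-rank chi-square by direct O-E/V table accumulation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g1 = np.asarray(group1_mask, dtype=bool)
    o_minus_e = 0.0
    v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e**2 / v) if v > 0 else 0.0
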
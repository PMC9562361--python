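"""Independent oracles used by the test suite.

Each oracle is a deliberately naive implementation (brute force,
enumeration, hand-rolled arithmetic) kept separate from the library code
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def wilcoxon_bruteforce(x, y) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^m sign patterns."""
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return 0.0, 1.0
    absd = np.abs(d)
    # average ranks
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(m)
    sa = absd[order]
    i = 0
    while i < m:
        j = i
        while j + 1 < m and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    dev = abs(w_obs - total / 2)
    count = 0
    for signs in itertools.product((0, 1), repeat=m):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - total / 2) >= dev - 1e-12:
            count += 1
    return w_obs, count / 2**m


def km_product_limit(times, events) -> list[tuple[float, float]]:
    """Hand-rolled product-limit estimator: [(event time, S)] steps."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    steps = []
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        steps.append((t, s))
    return steps


def logrank_chi2(times, events, groups) -> float:
    """Hand-rolled two-group log-rank chi-square (hypergeometric variance)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    g1 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = (times >= t).sum()
        n1 = (g1 & (times >= t)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        e1 = d * n1 / at_risk
        o_minus_e += d1 - e1
        if at_risk > 1:
            var += d * (n1 / at_risk) * (1 - n1 / at_risk) * (at_risk - d) / (at_risk - 1)
    return float(o_minus_e**2 / var)


def anova_f(groups: dict) -> float:
    """Hand-rolled one-way ANOVA F from sums of squares."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    grand = np.concatenate(arrays).mean()
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


def ks_uniform_pvalue(samples) -> float:
    """KS test of samples against U(0,1)."""
    from scipy import stats

    return float(stats.kstest(np.asarray(samples), "uniform").pvalue)
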
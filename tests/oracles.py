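"""Independent brute-force oracles used across the test suite.

These deliberately use explicit sums / enumeration rather than the
library code paths they are checking.
"""
import math

import numpy as np


def brute_force_pearson(x, y):
    """Explicit-sum Pearson oracle on complete pairs; returns (r, n)."""
    pairs = [(a, b) for a, b in zip(x, y) if not (math.isnan(a) or math.isnan(b))]
    n = len(pairs)
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    return sxy / math.sqrt(sxx * syy), n


def welch_t(a, b):
    """Textbook Welch t statistic and Satterthwaite df."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def oneway_anova_f(groups):
    """Explicit sums one-way ANOVA F statistic."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    return (ss_between / df1) / (ss_within / df2)


def km_survival(times, events):
    """Hand product-limit estimate: list of (event time, S(t))."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    surv = 1.0
    out = []
    distinct = sorted({times[i] for i in order if events[i] == 1})
    for t in distinct:
        at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        surv *= 1 - d / at_risk
        out.append((t, surv))
    return out


def logrank_chi2(times, events, groups):
    """O-E / hypergeometric-variance log-rank oracle for two groups."""
    uniq = sorted(set(groups))
    assert len(uniq) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({x for x, e in zip(times, events) if e == 1}):
        n_tot = sum(1 for x in times if x >= t)
        n1 = sum(1 for x, g in zip(times, groups) if x >= t and g == uniq[0])
        d_tot = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        d1 = sum(
            1
            for x, e, g in zip(times, events, groups)
            if x == t and e == 1 and g == uniq[0]
        )
        o_minus_e += d1 - d_tot * n1 / n_tot
        if n_tot > 1:
            var += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    return 0.0 if var == 0 else o_minus_e**2 / var


def cox_partial_loglik(beta, times, events, x):
    """Breslow-free partial log-likelihood for untied data, one covariate."""
    ll = 0.0
    for i, (t, e) in enumerate(zip(times, events)):
        if e != 1:
            continue
        risk = [j for j, tj in enumerate(times) if tj >= t]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll
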
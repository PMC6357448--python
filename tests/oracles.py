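"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's implementations: the log-rank oracle
tabulates 2x2 tables per event time with plain Python loops, the KM oracle
multiplies factors one by one, the KS oracle walks the whole ranking with
exact rational arithmetic, and the Fisher oracle sums hypergeometric tails.
"""

from fractions import Fraction

import numpy as np
from scipy import stats


def bruteforce_logrank(labels, times, events):
    """Direct summation of the log-rank 2x2 tables over distinct event times.

    Returns (chi2, o1, e1, o2, e2). Censored subjects at t stay at risk for
    events at t.
    """
    labels = list(labels)
    times = list(times)
    events = list(events)
    event_times = sorted({t for t, e in zip(times, events) if e == 1})
    num = 0.0
    var = 0.0
    o1 = e1 = o_tot = 0.0
    for tj in event_times:
        at_risk = [i for i, t in enumerate(times) if t >= tj]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if labels[i] == 1)
        d = sum(1 for i, (t, e) in enumerate(zip(times, events)) if t == tj and e == 1)
        d1 = sum(
            1
            for i, (t, e) in enumerate(zip(times, events))
            if t == tj and e == 1 and labels[i] == 1
        )
        exp1 = d * n1 / n
        num += d1 - exp1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        o1 += d1
        e1 += exp1
        o_tot += d
    chi2 = num**2 / var if var > 0 else float("nan")
    return chi2, o1, e1, o_tot - o1, o_tot - e1


def bruteforce_km(times, events):
    """Product-limit by explicit multiplication, one event time at a time."""
    event_times = sorted({t for t, e in zip(times, events) if e == 1})
    s = 1.0
    out = []
    for tj in event_times:
        n = sum(1 for t in times if t >= tj)
        d = sum(1 for t, e in zip(times, events) if t == tj and e == 1)
        s *= 1.0 - d / n
        out.append((tj, n, d, s))
    return out


def bruteforce_ks_es(positions, n):
    """Signed max |D| of the set-vs-uniform CDF difference, exact rationals."""
    pos = set(int(p) for p in positions)
    t = len(pos)
    c = 0
    mx = Fraction(0)
    mn = Fraction(0)
    for i in range(n + 1):
        if i in pos:
            c += 1
        d = Fraction(c, t) - Fraction(i, n)
        mx = max(mx, d)
        mn = min(mn, d)
    if mx > -mn:
        return float(mx)
    if -mn > mx:
        return float(mn)
    return 0.0


def bruteforce_ks_score(up_positions, down_positions, n):
    es_u = bruteforce_ks_es(up_positions, n)
    es_d = bruteforce_ks_es(down_positions, n)
    if es_u * es_d > 0:
        return 0.0
    return (es_u - es_d) / 2.0


def bruteforce_fisher_p(a, b, c, d):
    """Two-sided Fisher exact p for [[a, b], [c, d]] by tail summation over
    all tables with the same margins, including every table whose point
    probability does not exceed the observed one."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    obs = stats.hypergeom.pmf(a, n, row1, col1)
    p = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = stats.hypergeom.pmf(x, n, row1, col1)
        if px <= obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


def bruteforce_weighted_rank_corr(x, y, w):
    """Weighted Pearson correlation of rank vectors, written out longhand."""
    x = [float(v) for v in stats.rankdata(x)]
    y = [float(v) for v in stats.rankdata(y)]
    w = [float(v) for v in w]
    sw = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
    my = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / sw
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / sw
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / sw
    return cov / np.sqrt(vx * vy)


def bruteforce_anova_f(groups_of_values):
    """One-way ANOVA F from the explicit sum-of-squares table."""
    all_vals = [v for grp in groups_of_values for v in grp]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups_of_values)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups_of_values)
    dfb = len(groups_of_values) - 1
    dfw = len(all_vals) - len(groups_of_values)
    return (ssb / dfb) / (ssw / dfw)


def assign_group_by_rule_text(pten_low: bool, mir_low_flags, is_tnbc: bool) -> str:
    """The written a/b/c rule, transcribed independently: among PTEN-low
    TNBC tumors, low expression of four or all five miRNAs is group "a",
    high expression of all five or four (at most one low) is group "c",
    the remaining tumors are group "b"."""
    if not is_tnbc:
        return "non_tnbc"
    if not pten_low:
        return "pten_positive"
    n_low = sum(bool(f) for f in mir_low_flags)
    if n_low in (4, 5):
        return "a"
    if n_low in (0, 1):
        return "c"
    return "b"
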
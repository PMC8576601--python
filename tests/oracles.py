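"""Independent brute-force oracles used to verify the implementation.

Everything here is written as plain loops straight from the defining
formulas, deliberately ignoring the vectorized implementation paths.
"""

import math


def is_oracle(days):
    """days: list of 24-long lists. Printed IS formula, complete data."""
    flat = [v for day in days for v in day]
    n = len(flat)
    p = 24
    grand = sum(flat) / n
    profile = [sum(day[h] for day in days) / len(days) for h in range(p)]
    num = n * sum((m - grand) ** 2 for m in profile)
    den = p * sum((v - grand) ** 2 for v in flat)
    return num / den


def iv_oracle(flat):
    n = len(flat)
    grand = sum(flat) / n
    num = n * sum((flat[i] - flat[i - 1]) ** 2 for i in range(1, n))
    den = (n - 1) * sum((v - grand) ** 2 for v in flat)
    return num / den


def icv_oracle(days):
    """Mean over hours of across-day SD/mean (sample SD)."""
    total = 0.0
    for h in range(24):
        vals = [day[h] for day in days]
        m = sum(vals) / len(vals)
        var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
        total += math.sqrt(var) / m
    return total / 24


def m10_l5_ra_oracle(days):
    profile = [sum(day[h] for day in days) / len(days) for h in range(24)]
    wrap = profile + profile
    m10 = max(sum(wrap[s:s + 10]) / 10 for s in range(24))
    l5 = min(sum(wrap[s:s + 5]) / 5 for s in range(24))
    return m10, l5, (m10 - l5) / (m10 + l5)


def ac_oracle(flat, k):
    n = len(flat)
    grand = sum(flat) / n
    num = sum((flat[i] - grand) * (flat[i + k] - grand) for i in range(n - k))
    den = sum((v - grand) ** 2 for v in flat)
    return num / den


def rmssd_oracle(vals):
    diffs = [vals[i + 1] - vals[i] for i in range(len(vals) - 1)]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up adjustment by the textbook recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def confusion_oracle(tp, fp, fn, tn):
    total = tp + fp + fn + tn
    out = {"accuracy": (tp + tn) / total}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["ppv"] = tp / (tp + fp) if tp + fp else None
    out["npv"] = tn / (tn + fn) if tn + fn else None
    po = out["accuracy"]
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / total**2
    out["kappa"] = (po - pe) / (1 - pe) if pe != 1 else None
    return out


def midrank(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of midranks."""
    rx, ry = midrank(x), midrank(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def tukey_oracle(values, k=1.5):
    """Type-7 quartiles + Tukey fences, by direct interpolation."""
    s = sorted(values)
    n = len(s)

    def quantile(q):
        h = (n - 1) * q
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return [v < q1 - k * iqr or v > q3 + k * iqr for v in values]


def auc_mann_whitney(scores, labels):
    """AUC as the normalized Mann-Whitney U statistic (ties -> 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
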
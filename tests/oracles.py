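"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, enumeration) and
shares no code with the package implementation it checks.
"""

from collections import deque

import numpy as np


def neighbor_offsets(connectivity):
    """Explicit 3-D neighbour offsets for 6/18/26-connectivity."""
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((di, dj, dk))
    return offs


def flood_fill(supra, seed, connectivity):
    """BFS connected component of a boolean grid containing ``seed``."""
    shape = supra.shape
    out = np.zeros(shape, dtype=bool)
    if not supra[seed]:
        return out
    offs = neighbor_offsets(connectivity)
    q = deque([seed])
    out[seed] = True
    while q:
        i, j, k = q.popleft()
        for di, dj, dk in offs:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                if supra[ni, nj, nk] and not out[ni, nj, nk]:
                    out[ni, nj, nk] = True
                    q.append((ni, nj, nk))
    return out


def all_components(supra, connectivity):
    """All connected components of a boolean grid, as a list of masks in
    first-voxel scan order."""
    remaining = supra.copy()
    comps = []
    while remaining.any():
        seed = tuple(np.argwhere(remaining)[0])
        comp = flood_fill(remaining, seed, connectivity)
        comps.append(comp)
        remaining &= ~comp
    return comps


def centers_in_box(shape, spacing, origin, center, size):
    """Enumerate voxel indices whose centres lie in the closed box."""
    lo = np.asarray(center) - np.asarray(size) / 2
    hi = np.asarray(center) + np.asarray(size) / 2
    hits = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                pos = np.asarray(origin) + np.asarray([i, j, k]) * np.asarray(spacing)
                if np.all(pos >= lo - 1e-9) and np.all(pos <= hi + 1e-9):
                    hits.append((i, j, k))
    return hits


def quantile_interp(values, q):
    """Sort-and-interpolate quantile (linear between order statistics)."""
    xs = sorted(values)
    n = len(xs)
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def kendall_tau_enumerate(a, b):
    """Tau-b by exhaustive concordant/discordant pair counting."""
    n = len(a)
    conc = disc = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_a) * (n0 - ties_b))
    return (conc - disc) / denom


def km_by_hand(times, events):
    """Product-limit estimator as (event_times, survival) arrays."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    uniq = np.unique(times[events == 1])
    s = 1.0
    out_t, out_s = [], []
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Observed-minus-expected log-rank chi² (group A as index group)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_t = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        da = np.sum((ta == t) & (ea == 1))
        db = np.sum((tb == t) & (eb == 1))
        n, d = na + nb, da + db
        if n < 2:
            continue
        e_a = d * na / n
        o_minus_e += da - e_a
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def breslow_loglik_by_hand(beta, times, events, x):
    """Breslow partial log-likelihood evaluated by explicit loops."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def roc_table_enumerate(mtv, outcome):
    """Sens/spec at every unique threshold via explicit 2×2 tables."""
    rows = []
    for t in sorted(set(mtv)):
        tp = sum(1 for m, o in zip(mtv, outcome) if m >= t and o == 1)
        fn = sum(1 for m, o in zip(mtv, outcome) if m < t and o == 1)
        tn = sum(1 for m, o in zip(mtv, outcome) if m < t and o == 0)
        fp = sum(1 for m, o in zip(mtv, outcome) if m >= t and o == 0)
        rows.append((t, tp / (tp + fn), tn / (tn + fp)))
    return rows
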
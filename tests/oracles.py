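"""Independent brute-force reference implementations used by the tests.

These are deliberately naive (explicit Python loops, flood fill, O-E
accumulation) and share no code with the package's vectorized builders.
"""

from collections import deque
from itertools import product

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dz in (0, 1)
    for dy in ((-1, 0, 1) if dz == 1 else (0, 1))
    for dx in ((-1, 0, 1) if (dz == 1 or dy == 1) else (1,))
]
NEIGH_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inb(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_brute(labels, mask, G, distance=1):
    shape = labels.shape
    out = np.zeros((G, G), dtype=np.int64)
    for p in product(*map(range, shape)):
        if not mask[p]:
            continue
        for d in DIRS_13:
            for sgn in (1, -1):
                q = tuple(c + sgn * distance * dc for c, dc in zip(p, d))
                if _inb(q, shape) and mask[q]:
                    out[labels[p] - 1, labels[q] - 1] += 1
    return out


def glrlm_brute(labels, mask, G):
    shape = labels.shape
    runs = {}
    for d in DIRS_13:
        for p in product(*map(range, shape)):
            if not mask[p]:
                continue
            prev = tuple(c - dc for c, dc in zip(p, d))
            if _inb(prev, shape) and mask[prev] and labels[prev] == labels[p]:
                continue  # not a run start
            length, cur = 1, p
            while True:
                nxt = tuple(c + dc for c, dc in zip(cur, d))
                if _inb(nxt, shape) and mask[nxt] and labels[nxt] == labels[p]:
                    length, cur = length + 1, nxt
                else:
                    break
            runs[(labels[p], length)] = runs.get((labels[p], length), 0) + 1
    rmax = max(l for _, l in runs)
    out = np.zeros((G, rmax), dtype=np.int64)
    for (lv, l), c in runs.items():
        out[lv - 1, l - 1] += c
    return out


def glszm_brute(labels, mask, G):
    shape = labels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = {}
    for p in product(*map(range, shape)):
        if not mask[p] or visited[p]:
            continue
        lv = labels[p]
        queue = deque([p])
        visited[p] = True
        size = 0
        while queue:
            cur = queue.popleft()
            size += 1
            for d in NEIGH_26:
                q = tuple(c + dc for c, dc in zip(cur, d))
                if _inb(q, shape) and mask[q] and not visited[q] and labels[q] == lv:
                    visited[q] = True
                    queue.append(q)
        zones[(lv, size)] = zones.get((lv, size), 0) + 1
    smax = max(s for _, s in zones)
    out = np.zeros((G, smax), dtype=np.int64)
    for (lv, s), c in zones.items():
        out[lv - 1, s - 1] += c
    return out


def ngtdm_brute(labels, mask, G):
    shape = labels.shape
    s = np.zeros(G)
    cnt = np.zeros(G)
    n = 0
    for p in product(*map(range, shape)):
        if not mask[p]:
            continue
        nb = [
            labels[tuple(c + dc for c, dc in zip(p, d))]
            for d in NEIGH_26
            if _inb(tuple(c + dc for c, dc in zip(p, d)), shape)
            and mask[tuple(c + dc for c, dc in zip(p, d))]
        ]
        if not nb:
            continue
        n += 1
        cnt[labels[p] - 1] += 1
        s[labels[p] - 1] += abs(labels[p] - float(np.mean(nb)))
    p_occ = cnt / n if n else cnt
    return s, p_occ, n


def logrank_brute(time, event, group):
    """Two-group log-rank chi-square via explicit O-E tables."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    O = E = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def icc_anova_brute(R, model):
    """ICC from an explicitly assembled two-way ANOVA table."""
    R = np.asarray(R, float)
    n, k = R.shape
    grand = R.mean()
    ss_rows = k * sum((R[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((R[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((R - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "two_way_consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
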
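"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as simple nested-loop enumeration,
sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def harrell_cindex_bruteforce(scores, time, event) -> float:
    """Exhaustive pairwise Harrell C with higher score = higher risk.

    A pair (i, j) is comparable when the earlier observed time carries an
    event; concordance means the shorter survivor has the larger score,
    score ties count 1/2.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(scores)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # orient so i is the earlier time
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
            elif time[i] == time[j] and i < j and event[i] == 1 and event[j] == 1:
                # both die at the same time: any score ordering is half-credited
                den += 1
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def count_runs_bruteforce(levels: np.ndarray, off) -> list:
    """All maximal same-level runs along one direction, as (level, length)."""
    levels = np.asarray(levels)
    if levels.ndim == 2:
        levels = levels[..., None]
    shape = levels.shape
    runs = []
    for start in np.ndindex(shape):
        if levels[start] == 0:
            continue
        prev = tuple(np.subtract(start, off))
        in_bounds = all(0 <= p < s for p, s in zip(prev, shape))
        if in_bounds and levels[prev] == levels[start]:
            continue  # not a run start
        pos = start
        length = 0
        while all(0 <= p < s for p, s in zip(pos, shape)) and levels[pos] == levels[start]:
            length += 1
            pos = tuple(np.add(pos, off))
        runs.append((int(levels[start]), length))
    return runs


def count_zones_bruteforce(levels: np.ndarray) -> list:
    """All 26-connected equal-level zones, as (level, size), by DFS."""
    levels = np.asarray(levels)
    if levels.ndim == 2:
        levels = levels[..., None]
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    neighbors = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    zones = []
    for start in np.ndindex(shape):
        if levels[start] == 0 or seen[start]:
            continue
        level = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            pos = stack.pop()
            size += 1
            for d in neighbors:
                nb = tuple(np.add(pos, d))
                if all(0 <= p < s for p, s in zip(nb, shape)) and not seen[nb] and levels[nb] == level:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((int(level), size))
    return zones


def standard_logrank_bruteforce(time, event, group):
    """Standard (unweighted) two-group log-rank chi-square, coded directly."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = np.unique(group)
    assert labels.size == 2
    g1 = group == labels[0]
    obs_minus_exp = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs_minus_exp**2 / var


def icc_absolute_agreement_anova(table: np.ndarray) -> float:
    """ICC(A,1) from explicit two-way ANOVA mean squares on an n x 2 table."""
    table = np.asarray(table, float)
    n, k = table.shape
    grand = table.mean()
    ss_rows = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err))


def km_survival_bruteforce(times, events):
    """Product-limit curve by direct multiplication at each event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
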
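"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit pair enumeration and
from-scratch recomputation, pure Python, no shared code with the package
internals beyond the public data containers.
"""

from itertools import combinations

import numpy as np


def gehan_u_oracle(times, events):
    """O(m^2) Gehan U-scores by explicit pair enumeration."""
    m = len(times)
    u = np.zeros(m, dtype=int)
    for s in range(m):
        for t in range(m):
            if s == t:
                continue
            # s definitively outlives t
            if (times[s] > times[t] and events[t] == 1) or (
                times[s] == times[t] and events[s] == 0 and events[t] == 1
            ):
                u[s] += 1
            # s definitively dies before t
            if (times[t] > times[s] and events[s] == 1) or (
                times[t] == times[s] and events[t] == 0 and events[s] == 1
            ):
                u[s] -= 1
    return u


def gehan_w_oracle(ta, ea, tb, eb):
    """Gehan statistic W and effect size from the pair-enumeration oracle."""
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    u = gehan_u_oracle(times, events)
    na, nb = len(ta), len(tb)
    n = na + nb
    w = float(u[:na].sum())
    var = na * nb * float((u.astype(float) ** 2).sum()) / (n * (n - 1))
    if var <= 0:
        return w, var, 0.0
    return w, var, abs(w / np.sqrt(var)) / np.sqrt(n)


def harrell_c_oracle(risk, times, events):
    """All-ordered-pairs Harrell concordance with explicit tie rules."""
    n = len(times)
    conc = disc = tied = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not comparable:
                continue
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                tied += 1
            else:
                disc += 1
    total = conc + disc + tied
    c = (conc + 0.5 * tied) / total if total else None
    return c, conc, disc, tied, total


def logrank_oracle(ta, ea, tb, eb):
    """(O_a - E_a, variance) by per-event-time 2x2 table summation."""
    event_times = sorted(set(list(ta[ea == 1]) + list(tb[eb == 1])))
    stat = 0.0
    var = 0.0
    for s in event_times:
        n1 = int((ta >= s).sum())
        n2 = int((tb >= s).sum())
        d1 = int(((ta == s) & (ea == 1)).sum())
        d2 = int(((tb == s) & (eb == 1)).sum())
        nj, dj = n1 + n2, d1 + d2
        stat += d1 - dj * n1 / nj
        if nj > 1:
            var += dj * (n1 / nj) * (n2 / nj) * (nj - dj) / (nj - 1)
    return stat, var


def minimax_linkage_oracle(d):
    """From-scratch minimax agglomeration.

    Returns [(left_id, right_id, height, prototype, members)] with node ids
    in creation order (leaves 0..n-1), recomputing every candidate radius at
    every step; ties break exactly as specified (smallest radius, then
    lexicographically smallest id pair; prototype = lowest attaining index).
    """
    n = len(d)
    members = {i: [i] for i in range(n)}
    active = list(range(n))
    merges = []
    for step in range(n - 1):
        best = None
        for i, j in combinations(sorted(active), 2):
            union = sorted(members[i] + members[j])
            radius, proto = None, None
            for x in union:
                mx = max(d[x][y] for y in union)
                if radius is None or mx < radius:
                    radius, proto = mx, x
            if best is None or radius < best[0]:
                best = (radius, i, j, proto)
        radius, i, j, proto = best
        node = n + step
        members[node] = sorted(members[i] + members[j])
        active = [x for x in active if x not in (i, j)] + [node]
        merges.append((i, j, radius, proto, tuple(members[node])))
    return merges


def pam_cost(d, medoids):
    return sum(min(d[i][m] for m in medoids) for i in range(len(d)))


def pam_exhaustive_oracle(d, k):
    """Globally optimal medoid set by exhaustive search; ties pick the
    lexicographically smallest set."""
    best_set, best_cost = None, None
    for medoids in combinations(range(len(d)), k):
        cost = pam_cost(d, medoids)
        if best_cost is None or cost < best_cost - 1e-12:
            best_set, best_cost = medoids, cost
    return list(best_set), best_cost
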
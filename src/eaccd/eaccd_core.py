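"""The ensemble clustering engine.

Three steps turn a set of combination cohorts into a dendrogram:

1. **Initial dissimilarity** — the Gehan–Wilcoxon effect size between every
   pair of cohorts' survival samples.
2. **Ensemble learning** — for each k in 1..n, partition the combinations
   into k clusters with PAM (BUILD + SWAP) on the initial dissimilarities;
   the learned dissimilarity is the weighted fraction of partitions that
   separate a pair, dis(i, j) = sum_k w_k * delta_k(i, j), with uniform
   weights w_k = 1/n by default.
3. **Minimax-linkage hierarchical clustering** of the learned
   dissimilarities: at every step merge the cluster pair whose union has
   the smallest minimax radius min_x max_y d(x, y); the attaining center is
   the cluster's prototype.

Cutting the dendrogram at g groups, ordering groups by survival and scoring
the ordering with Harrell's C yields the C-index-vs-groups curve whose knee
selects the number of prognostic groups.

Every stage is deterministic: all ties (medoid assignment, swap selection,
merge-pair selection, prototypes) break by lowest index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations as iter_pairs

import numpy as np
import pandas as pd

from .cohort import CombinationSet
from .survival_stats import (
    gehan_effect_size,
    harrell_c,
    km_curve,
    pool_samples,
    rmst,
)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Labeled symmetric nonnegative matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match the label count")
        if (v < 0).any():
            raise ValueError("dissimilarities must be nonnegative")
        if np.abs(np.diag(v)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("matrix must be symmetric to 1e-12")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    prototype: int


@dataclass(frozen=True)
class Dendrogram:
    """Minimax-linkage merge tree.

    Node ids: leaves are 0..n-1 in label order; the i-th merge creates node
    n + i.  Heights are minimax radii; the prototype is the leaf attaining
    the radius of the merged cluster (lowest index on ties).
    """

    merges: tuple[Merge, ...]
    leaves: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.leaves)

    def to_dict(self) -> dict:
        return {
            "leaves": list(self.leaves),
            "merges": [[m.left, m.right, m.height, m.prototype] for m in self.merges],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Dendrogram":
        return cls(
            merges=tuple(Merge(int(l), int(r), float(h), int(p)) for l, r, h, p in doc["merges"]),
            leaves=tuple(doc["leaves"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        heights = {i: 0.0 for i in range(self.n)}
        children: dict[int, tuple[int, int]] = {}
        for i, m in enumerate(self.merges):
            node = self.n + i
            heights[node] = m.height
            children[node] = (m.left, m.right)

        def render(node: int, parent_height: float) -> str:
            branch = parent_height - heights[node]
            if node < self.n:
                return f"{self.leaves[node]}:{branch:g}"
            l, r = children[node]
            h = heights[node]
            return f"({render(l, h)},{render(r, h)}):{branch:g}"

        root = self.n + len(self.merges) - 1
        l, r = children[root]
        h = heights[root]
        return f"({render(l, h)},{render(r, h)});"


@dataclass(frozen=True)
class CIndexCurve:
    """C-index against number of groups; g strictly increasing."""

    points: tuple[tuple[int, float], ...]

    def groups(self) -> np.ndarray:
        return np.array([g for g, _ in self.points])

    def cvalues(self) -> np.ndarray:
        return np.array([c for _, c in self.points])

    def at(self, g: int) -> float:
        for gg, c in self.points:
            if gg == g:
                return c
        raise KeyError(g)


def initial_dissimilarity_matrix(combos: CombinationSet) -> DissimilarityMatrix:
    """Pairwise Gehan–Wilcoxon effect sizes between combination cohorts."""
    n = combos.n
    if n < 2:
        raise ValueError("clustering needs at least two combinations")
    samples = [c.sample() for c in combos.cohorts]
    values = np.zeros((n, n))
    for i, j in iter_pairs(range(n), 2):
        d = gehan_effect_size(samples[i], samples[j]).effect_size
        values[i, j] = values[j, i] = d
    return DissimilarityMatrix(combos.labels, values)


_EPS = 1e-12


def pam_medoids(
    D: DissimilarityMatrix, k: int, max_swap_iters: int = 200
) -> tuple[list[int], list[float]]:
    """PAM BUILD + SWAP medoids and the objective trace across SWAP steps.

    BUILD greedily adds the medoid giving the largest cost reduction; SWAP
    repeatedly applies the single best strictly-improving medoid/non-medoid
    exchange.  Deterministic: all ties break by lowest index.
    """
    d = D.values
    n = D.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    if k == n:
        return list(range(n)), [0.0]

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    dnear = d[:, medoids[0]].copy()
    while len(medoids) < k:
        cand = np.array([i for i in range(n) if i not in medoids])
        costs = np.minimum(dnear[:, None], d[:, cand]).sum(axis=0)
        best = int(cand[int(np.argmin(costs))])
        medoids.append(best)
        dnear = np.minimum(dnear, d[:, best])
    medoids = sorted(medoids)

    trace = [float(d[:, medoids].min(axis=1).sum())]
    for _ in range(max_swap_iters):
        cost = trace[-1]
        med = np.array(medoids)
        nonmed = np.array([i for i in range(n) if i not in medoids])
        if len(nonmed) == 0:
            break
        best_cost, best_swap = cost, None
        for mi in range(len(medoids)):
            others = med[np.arange(len(med)) != mi]
            drest = d[:, others].min(axis=1) if len(others) else np.full(n, np.inf)
            newcosts = np.minimum(drest[:, None], d[:, nonmed]).sum(axis=0)
            j = int(np.argmin(newcosts))
            if newcosts[j] < best_cost - _EPS:
                best_cost = float(newcosts[j])
                best_swap = (mi, int(nonmed[j]))
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)
        trace.append(float(d[:, medoids].min(axis=1).sum()))
    return medoids, trace


def pam_partition(D: DissimilarityMatrix, k: int, max_swap_iters: int = 200) -> np.ndarray:
    """Cluster labels 0..k-1: each item joins its nearest medoid (lowest index on ties)."""
    medoids, _ = pam_medoids(D, k, max_swap_iters)
    return np.argmin(D.values[:, medoids], axis=1)


@dataclass(frozen=True)
class PartitionEnsemble:
    """Per-k PAM partitions of one dissimilarity matrix."""

    labels_by_k: dict[int, np.ndarray]

    def delta(self, k: int) -> np.ndarray:
        """delta_k(i, j) = 1 iff i and j are in different clusters at k."""
        lab = self.labels_by_k[k]
        return (lab[:, None] != lab[None, :]).astype(float)


def pam_ensemble(
    D: DissimilarityMatrix,
    k_range: tuple[int, int] | None = None,
    max_swap_iters: int = 200,
) -> PartitionEnsemble:
    """Run PAM for every k in ``k_range`` (default the full range 1..n).

    k = 1 and k = n are forced partitions and are filled in without PAM.
    """
    n = D.n
    k_lo, k_hi = k_range if k_range is not None else (1, n)
    if not 1 <= k_lo <= k_hi <= n:
        raise ValueError(f"k_range ({k_lo}, {k_hi}) not within [1, {n}]")
    labels: dict[int, np.ndarray] = {}
    for k in range(k_lo, k_hi + 1):
        if k == 1:
            labels[k] = np.zeros(n, dtype=int)
        elif k == n:
            labels[k] = np.arange(n)
        else:
            labels[k] = pam_partition(D, k, max_swap_iters)
    return PartitionEnsemble(labels)


def ensemble_dissimilarity(
    D: DissimilarityMatrix,
    k_range: tuple[int, int] | None = None,
    weights: np.ndarray | None = None,
    max_swap_iters: int = 200,
) -> DissimilarityMatrix:
    """Learned dissimilarity dis(i, j) = sum_k w_k * delta_k(i, j).

    Default weights are uniform over the k-range (w_k = 1/n for the full
    range), so with the full range every off-diagonal entry lies in
    [1/n, (n-1)/n]: k = 1 never separates a pair and k = n always does.
    """
    n = D.n
    k_lo, k_hi = k_range if k_range is not None else (1, n)
    ens = pam_ensemble(D, (k_lo, k_hi), max_swap_iters)
    ks = list(range(k_lo, k_hi + 1))
    if weights is None:
        w = np.full(len(ks), 1.0 / len(ks))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(ks):
            raise ValueError("one weight per k is required")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
    values = np.zeros((n, n))
    for wk, k in zip(w, ks):
        values += wk * ens.delta(k)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DissimilarityMatrix(D.labels, values)


def _minimax_radius(d: np.ndarray, members: tuple[int, ...]) -> tuple[float, int]:
    """(min_x max_y d(x, y), attaining x) over a sorted member tuple."""
    idx = np.array(members)
    sub = d[np.ix_(idx, idx)]
    maxima = sub.max(axis=1)
    a = int(np.argmin(maxima))  # first minimum -> lowest leaf index
    return float(maxima[a]), int(idx[a])


def minimax_linkage(D: DissimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering under the minimax-linkage criterion.

    Merge heights are minimax radii of the merged clusters; pair ties break
    by the lexicographically smallest (left, right) pair of node ids in
    cluster-creation order.
    """
    n = D.n
    if n < 2:
        raise ValueError("clustering needs at least two leaves")
    d = D.values
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    active: list[int] = list(range(n))
    cache: dict[tuple[int, int], tuple[float, int]] = {}

    def pair_radius(i: int, j: int) -> tuple[float, int]:
        key = (i, j)
        if key not in cache:
            union = tuple(sorted(members[i] + members[j]))
            cache[key] = _minimax_radius(d, union)
        return cache[key]

    merges: list[Merge] = []
    for step in range(n - 1):
        best: tuple[int, int] | None = None
        best_r = np.inf
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                i, j = active[a_pos], active[b_pos]
                r, _ = pair_radius(i, j)
                if r < best_r:
                    best_r, best = r, (i, j)
        assert best is not None
        i, j = best
        r, proto = pair_radius(i, j)
        node = n + step
        merges.append(Merge(i, j, r, proto))
        members[node] = tuple(sorted(members[i] + members[j]))
        active = [x for x in active if x not in (i, j)] + [node]
    return Dendrogram(tuple(merges), D.labels)


def cut_dendrogram(dendro: Dendrogram, g: int) -> np.ndarray:
    """Partition into g clusters by undoing the last g - 1 merges.

    Returns labels 1..g assigned in leaf order (the cluster of the first
    leaf is 1, the next new cluster 2, and so on).
    """
    n = dendro.n
    if not 1 <= g <= n:
        raise ValueError(f"g={g} out of range [1, {n}]")
    parent = list(range(n + len(dendro.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - g):
        m = dendro.merges[step]
        node = n + step
        parent[find(m.left)] = node
        parent[find(m.right)] = node

    labels = np.zeros(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels[leaf] = seen[root]
    return labels


def order_groups(
    labels: np.ndarray, combos: CombinationSet, horizon: float
) -> np.ndarray:
    """Renumber cluster labels so group 1 has the best pooled survival.

    Groups are ranked by decreasing restricted mean survival time at
    ``horizon``; ties by Kaplan–Meier survival at the horizon, then by the
    smallest original label.
    """
    labels = np.asarray(labels)
    if len(labels) != combos.n:
        raise ValueError("one label per combination is required")
    keys = []
    for lab in np.unique(labels):
        pooled = pool_samples(*(c.sample() for c, l in zip(combos.cohorts, labels) if l == lab))
        curve = km_curve(pooled)
        keys.append((-rmst(curve, horizon), -curve.survival_at(horizon), lab))
    ranking = {lab: i + 1 for i, (_, _, lab) in enumerate(sorted(keys))}
    return np.array([ranking[l] for l in labels])


def cindex_curve(
    dendro: Dendrogram,
    combos: CombinationSet,
    g_range: tuple[int, int],
    ordering_horizon: float,
) -> CIndexCurve:
    """C-index of the survival-ordered g-group partition, for each g in range."""
    g_lo, g_hi = g_range
    if not 2 <= g_lo <= g_hi <= dendro.n:
        raise ValueError(f"g_range ({g_lo}, {g_hi}) not within [2, {dendro.n}]")
    pooled = pool_samples(*(c.sample() for c in combos.cohorts))
    sizes = [c.size for c in combos.cohorts]
    points = []
    for g in range(g_lo, g_hi + 1):
        ordered = order_groups(cut_dendrogram(dendro, g), combos, ordering_horizon)
        risk = np.repeat(ordered, sizes)
        points.append((g, harrell_c(risk, pooled).c))
    return CIndexCurve(tuple(points))


def knee_point(curve: CIndexCurve) -> int:
    """Knee of the C-index curve: the interior point farthest from the chord.

    Maximizes the perpendicular distance from (g, c_g) to the straight line
    joining the curve's first and last points; ties go to the smallest g.
    """
    pts = curve.points
    if len(pts) < 3:
        raise ValueError("knee detection needs at least 3 points; choose g manually")
    g0, c0 = pts[0]
    g1, c1 = pts[-1]
    dg, dc = g1 - g0, c1 - c0
    norm = float(np.hypot(dg, dc))
    best_g, best_d = pts[1][0], -1.0
    for g, c in pts[1:-1]:
        dist = abs(dg * (c - c0) - dc * (g - g0)) / norm
        if dist > best_d + _EPS:
            best_d, best_g = dist, g
    return int(best_g)
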
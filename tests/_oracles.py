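"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and recomputes from first
principles: character-by-character sequence scans, exhaustive
combinatorial enumeration, from-scratch distance recomputation at
every agglomeration step. Nothing imports the code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def naive_site_patterns(mature: str) -> dict:
    """Site patterns rebuilt by hand from the mature sequence."""
    mature = mature.upper().replace("U", "T")
    seed7 = mature[1:8]
    seed6 = mature[1:7]
    m8 = naive_revcomp(seed7)
    six = naive_revcomp(seed6)
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": six + "A", "6mer": six}


def naive_find_sites(utr: str, mature: str) -> list[tuple[str, int, int]]:
    """Position-by-position scan, strongest type first, with
    containment suppression: a weaker match inside a kept stronger
    site's interval is dropped. Returns (type, start, end) sorted by
    (start, strength)."""
    utr = utr.upper().replace("U", "T")
    patterns = naive_site_patterns(mature)
    order = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    kept = []
    stronger_intervals: list[tuple[int, int]] = []
    for st in order:
        pat = patterns[st]
        L = len(pat)
        new = []
        for start in range(len(utr) - L + 1):
            window = utr[start:start + L]
            if "N" in window:
                continue
            if window != pat:
                continue
            end = start + L
            if any(a <= start and end <= b for a, b in stronger_intervals):
                continue
            kept.append((st, start, end))
            new.append((start, end))
        stronger_intervals.extend(new)
    rank = {st: i for i, st in enumerate(order)}
    kept.sort(key=lambda s: (s[1], rank[s[0]]))
    return kept


def enum_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    pop = [1] * K + [0] * (N - K)
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(pop[i] for i in draw) >= k:
            hits += 1
    return hits / total if total else 1.0


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by explicit sort-and-scan."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


def welch_t_pvalue(x, y) -> float:
    """Welch two-sample t-test written out from the textbook formulas."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(2 * stats.t.sf(abs(t), df)), float(t)


def naive_hcluster(X: np.ndarray, metric: str = "correlation", linkage: str = "average"):
    """O(n^3) agglomeration recomputing cluster distances from the
    original pairwise matrix at every step.

    Ties: the pair whose smaller minimum original index (then larger)
    is lowest wins; left child is the cluster with the smaller
    minimum original index. Returns merges as (left, right,
    similarity) with node numbering: leaves 0..L-1, merge j -> L+j.
    """
    L = X.shape[0]
    if metric == "correlation":
        C = X - X.mean(axis=1, keepdims=True)
        D = np.empty((L, L))
        for i in range(L):
            for j in range(L):
                denom = math.sqrt((C[i] ** 2).sum() * (C[j] ** 2).sum())
                D[i, j] = 1.0 - max(-1.0, min(1.0, float((C[i] * C[j]).sum() / denom)))
    elif metric == "euclidean":
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    else:
        raise ValueError(metric)

    clusters = {i: ([i], i) for i in range(L)}  # key -> (members, node id)
    merges = []
    next_node = L
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for a, b in combinations(keys, 2):
            ma, mb = clusters[a][0], clusters[b][0]
            if linkage == "average":
                d = float(np.mean([D[i, j] for i in ma for j in mb]))
            elif linkage == "single":
                d = float(min(D[i, j] for i in ma for j in mb))
            else:
                d = float(max(D[i, j] for i in ma for j in mb))
            key = (d, min(min(ma), min(mb)), max(min(ma), min(mb)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (_d, _mi, _mj), a, b = best
        ma, mb = clusters[a], clusters[b]
        if min(ma[0]) <= min(mb[0]):
            left, right = ma, mb
        else:
            left, right = mb, ma
        merges.append((left[1], right[1], 1.0 - _d))
        members = ma[0] + mb[0]
        del clusters[a], clusters[b]
        clusters[next_node] = (members, next_node)
        next_node += 1
    return merges
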
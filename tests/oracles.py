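"""Independent brute-force oracles used only by the test suite.

These enumerate the full search space directly from the objective
definitions and stay independent of the dynamic programs they check.
"""

from __future__ import annotations

import numpy as np

from simseg import ScoringModel


def brute_cluster_score(scoring: ScoringModel, n: int) -> float:
    """Best objective over all segmentations x cluster assignments.

    Enumerates every breakpoint set and, per segmentation, every cluster
    assignment with distinct consecutive clusters, scoring incrementally:

        M + sum_h [ s(I_h, a_h) + bonus(a_h) - penalty(a_h) ]
    """
    w = scoring.position_scores[:n]
    K1 = w.shape[1]
    cs = np.zeros((n + 1, K1))
    np.cumsum(w, axis=0, out=cs[1:])
    pen = np.full(K1, scoring.M)
    pen[0] = scoring.penalty0
    bonus = np.zeros(K1)
    bonus[0] = scoring.nuisance_bonus

    best = -np.inf
    for mask in range(1 << (n - 1)):
        bounds = [0]
        bounds += [j + 1 for j in range(n - 1) if mask >> j & 1]
        bounds.append(n)
        ell = len(bounds) - 1
        # interval scores per candidate cluster
        s = [cs[bounds[h + 1]] - cs[bounds[h]] + bonus - pen for h in range(ell)]

        def dfs(h: int, last: int, acc: float) -> float:
            if h == ell:
                return acc
            out = -np.inf
            for a in range(K1):
                if a == last:
                    continue
                v = dfs(h + 1, a, acc + s[h][a])
                if v > out:
                    out = v
            return out

        total = dfs(0, -1, scoring.M)
        if total > best:
            best = total
    return float(best)


def brute_kmeans_2partition(X: np.ndarray) -> frozenset:
    """Optimal 2-partition minimizing within-cluster sum of squares.

    Exhaustive over all 2^(n-1) splits; returns one side as a frozenset of
    row indices.
    """
    n = X.shape[0]
    best = None
    best_wss = np.inf
    for mask in range(1, 1 << (n - 1)):  # point 0 fixed in side A
        b = [i for i in range(1, n) if (mask >> (i - 1)) & 1]
        a = [i for i in range(n) if i not in b]
        wss = 0.0
        for idx in (a, b):
            pts = X[idx]
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        if wss < best_wss:
            best_wss = wss
            best = frozenset(a)
    return best


def brute_recovery(queries, targets):
    """All-pairs best-hit recovery, written from the definitions.

    Returns (per-target list of (n_hits, J, R), micro J_tot).
    """
    rows = []
    inter_sum = union_sum = 0
    for t in targets:
        tpos = set(range(t.start, t.end + 1))
        hits = []
        for q in queries:
            if (q.chromosome, q.strand) != (t.chromosome, t.strand):
                continue
            qpos = set(range(q.start, q.end + 1))
            inter = len(tpos & qpos)
            if inter:
                hits.append((inter / len(tpos | qpos), -q.start, inter, len(qpos)))
        if not hits:
            rows.append((0, 0.0, None))
            continue
        hits.sort(reverse=True)
        J, _, inter, qlen = hits[0]
        rows.append((len(hits), J, qlen / len(tpos)))
        inter_sum += inter
        union_sum += qlen + len(tpos) - inter
    jtot = inter_sum / union_sum if union_sum else 0.0
    return rows, jtot
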
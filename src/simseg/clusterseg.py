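"""Fast clustering-based segmentation by dynamic programming.

After coarse-graining the signal into K clusters plus a nuisance bin, the
optimal segmentation with per-interval cluster assignments maximizes

    S(k, alpha) = max_{i <= k} max_{beta != alpha} S(i-1, beta)
                  + s(i, k, alpha) - M_alpha ,        S(0, beta) = M,

where ``s(i, k, alpha)`` totals per-position similarities of the interval
``[i, k]`` to cluster alpha and ``M_alpha`` is the jump penalty (``M`` for
real clusters, ``M0`` for jumps into the nuisance cluster).  Because
``s(i, k, a) = s(1, k, a) - s(1, i-1, a)`` is separable into prefix sums,
the inner maximum can be maintained as a running maximum per target
cluster, giving an O(nN) solver (:func:`segment`).  :func:`segment_naive`
evaluates the recursion directly in O(n^2 N) as the correctness reference.

Scoring functions (per-position similarity sigma~ of position i to cluster
alpha):

* ``ccls``: 1 if the position's own cluster equals alpha, else ``a`` (< 0);
* ``icor``: phi_eps of the Pearson correlation between the position's
  feature row and the cluster-alpha mean;
* ``ccor``: phi_eps of the correlation between the position's own cluster
  mean and the cluster-alpha mean;

with phi_eps(t) = sign(t) |t|^eps suppressing moderate correlations as eps
grows.  Two nuisance parametrizations are provided: the default sets
``s(i, k, 0) = M`` (compensating the jump penalty, so nuisance stretches
are score-neutral), the ``nu`` variant scores the nuisance column +nu for
nuisance-labelled positions and -nu otherwise (nu > 1 enforces breaks at
transitions into noisy, low-expressed regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .clustering import ClusterModel
from .segments import Segment, Segmentation

ScoringFunction = Literal["ccls", "icor", "ccor"]
NuisanceMode = Literal["compensate", "nu"]


def phi_transform(t, epsilon: float):
    """phi_eps(t) = sign(t) |t|^eps on [-1, 1]; odd, monotone, phi_1 = id."""
    if epsilon < 1:
        raise ValueError("epsilon must be >= 1")
    arr = np.asarray(t, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("phi_transform requires |t| <= 1")
    arr = np.clip(arr, -1.0, 1.0)
    out = np.sign(arr) * np.abs(arr) ** epsilon
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


@dataclass
class ScoringModel:
    """Scoring function, its parameters, and the per-position score matrix.

    ``position_scores`` has one row per position and K+1 columns; column 0
    is the nuisance cluster.  In the default ``compensate`` nuisance mode
    column 0 is all zero and every nuisance segment receives a flat bonus
    of M instead (score-neutral nuisance stretches).
    """

    function: ScoringFunction = "icor"
    a: float = -1.0  # ccls mismatch score, < 0
    epsilon: float = 1.0  # phi exponent, >= 1
    nu: float = 1.0  # nuisance similarity (nu mode)
    M: float = 100.0  # jump penalty
    M0: Optional[float] = None  # nuisance jump penalty; defaults to M
    nuisance_mode: NuisanceMode = "compensate"
    scale01: bool = False  # affine rescale of position_scores into [0, 1]
    position_scores: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.function not in ("ccls", "icor", "ccor"):
            raise ValueError(f"unknown scoring function {self.function!r}")
        if self.a >= 0:
            raise ValueError("ccls mismatch score a must be < 0")
        if self.epsilon < 1:
            raise ValueError("epsilon must be >= 1")
        if self.M < 0 or (self.M0 is not None and self.M0 < 0):
            raise ValueError("penalties must be >= 0")
        if self.nuisance_mode not in ("compensate", "nu"):
            raise ValueError(f"unknown nuisance mode {self.nuisance_mode!r}")

    @property
    def penalty0(self) -> float:
        return self.M if self.M0 is None else self.M0

    @property
    def nuisance_bonus(self) -> float:
        """Flat per-segment score of a nuisance segment (compensate mode)."""
        return self.M if self.nuisance_mode == "compensate" else 0.0

    @property
    def K(self) -> int:
        if self.position_scores is None:
            raise ValueError("position_scores not filled")
        return self.position_scores.shape[1] - 1


def build_position_scores(model: ClusterModel, scoring: ScoringModel) -> ScoringModel:
    """Fill ``scoring.position_scores`` (n x (K+1)) from a cluster model.

    phi_eps applies only to correlation-derived entries, never to the
    constants a and nu.
    """
    n, K = model.n, model.K
    labels = model.labels
    scores = np.zeros((n, K + 1))
    if scoring.function == "ccls":
        for alpha in range(1, K + 1):
            scores[:, alpha] = np.where(labels == alpha, 1.0, scoring.a)
    elif scoring.function == "icor":
        if model.pos_cluster_sim is None:
            raise ValueError("icor needs pos_cluster_sim")
        scores[:, 1:] = phi_transform(model.pos_cluster_sim, scoring.epsilon)
    elif scoring.function == "ccor":
        if model.cluster_cluster_sim is None:
            raise ValueError("ccor needs cluster_cluster_sim")
        Q = phi_transform(model.cluster_cluster_sim, scoring.epsilon)
        labeled = labels >= 1
        scores[labeled, 1:] = Q[labels[labeled] - 1]
        # nuisance-labelled positions: Q(0, alpha) = -nu for real alpha
        scores[~labeled, 1:] = -scoring.nu if scoring.nuisance_mode == "nu" else scoring.a
    if scoring.nuisance_mode == "nu":
        scores[:, 0] = np.where(labels == 0, scoring.nu, -scoring.nu)
    else:
        scores[:, 0] = 0.0  # flat per-segment bonus M handled by the DP
    if scoring.scale01:
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
        else:
            scores = np.zeros_like(scores)
    scoring.position_scores = scores
    return scoring


def _prefix_scores(scoring: ScoringModel) -> np.ndarray:
    """cs[k, alpha] = s(1, k, alpha); cs[0] = 0.  Column 0 is zero in
    compensate mode (the flat bonus is added per segment instead)."""
    w = scoring.position_scores
    cs = np.zeros((w.shape[0] + 1, w.shape[1]))
    np.cumsum(w, axis=0, out=cs[1:])
    return cs


def objective_score(scoring: ScoringModel, seg: Segmentation) -> float:
    """Evaluate the DP objective for an arbitrary segmentation.

    Equals M + sum_h (s(I_h, alpha_h) - M_{alpha_h}); the leading M mirrors
    the DP initialization S(0, beta) = M that compensates the first jump.
    """
    cs = _prefix_scores(scoring)
    total = scoring.M
    for seg_h in seg.segments:
        alpha = seg_h.cluster
        if alpha == 0:
            total += scoring.nuisance_bonus
            total += cs[seg_h.end, 0] - cs[seg_h.start - 1, 0]
            total -= scoring.penalty0
        else:
            total += cs[seg_h.end, alpha] - cs[seg_h.start - 1, alpha]
            total -= scoring.M
    return float(total)


def _interval_scores(scoring: ScoringModel, seg: Segmentation) -> None:
    cs = _prefix_scores(scoring)
    for s in seg.segments:
        base = cs[s.end, s.cluster] - cs[s.start - 1, s.cluster]
        if s.cluster == 0:
            base += scoring.nuisance_bonus
        s.score = float(base)


def _top_two(vals: np.ndarray) -> tuple[float, int, float, int]:
    """Best and second-best entries; ties -> smallest index."""
    b1 = int(np.argmax(vals))
    v1 = vals[b1]
    tmp = vals.copy()
    tmp[b1] = -np.inf
    b2 = int(np.argmax(tmp))
    return float(v1), b1, float(tmp[b2]), b2


def segment(scoring: ScoringModel, n: Optional[int] = None) -> Segmentation:
    """O(nN) DP via running maxima over the prefix-sum identity.

    Ties among co-optimal predecessors prefer smaller i (a longer last
    segment), then the smaller cluster index.
    """
    w = scoring.position_scores
    if w is None:
        raise ValueError("position_scores not filled")
    if n is None:
        n = w.shape[0]
    if n == 0:
        return Segmentation(n=0, segments=[], score=0.0)
    w = w[:n]
    K1 = w.shape[1]
    cs = np.zeros((n + 1, K1))
    np.cumsum(w, axis=0, out=cs[1:])
    pen = np.full(K1, scoring.M)
    pen[0] = scoring.penalty0
    bonus = np.zeros(K1)
    bonus[0] = scoring.nuisance_bonus

    S_prev = np.full(K1, scoring.M)  # S(0, beta) = M
    R = np.full(K1, -np.inf)  # running max_i of B_alpha(i-1) - cs[i-1, alpha]
    Rarg = [(0, 0)] * K1  # (i-1, beta) realizing R[alpha]
    bp = np.empty((n + 1, K1, 2), dtype=np.int64)  # backpointer (i, beta)
    alphas = np.arange(K1)
    for k in range(1, n + 1):
        j = k - 1
        v1, b1, v2, b2 = _top_two(S_prev)
        B = np.full(K1, v1)
        Barg = np.full(K1, b1)
        B[b1] = v2
        Barg[b1] = b2
        cand = B - cs[j]
        upd = cand > R
        R[upd] = cand[upd]
        for alpha in alphas[upd]:
            Rarg[alpha] = (k, int(Barg[alpha]))
        S_prev = R + cs[k] + bonus - pen
        bp[k, :, 0] = [Rarg[a][0] for a in range(K1)]
        bp[k, :, 1] = [Rarg[a][1] for a in range(K1)]

    alpha = int(np.argmax(S_prev))
    best = float(S_prev[alpha])
    segs: list[Segment] = []
    k = n
    while k > 0:
        i, beta = int(bp[k, alpha, 0]), int(bp[k, alpha, 1])
        segs.append(Segment(i, k, cluster=alpha))
        k = i - 1
        alpha = beta
    segs.reverse()
    out = Segmentation(n=n, segments=segs, score=best)
    _interval_scores(scoring, out)
    return out


def segment_naive(scoring: ScoringModel, n: Optional[int] = None) -> Segmentation:
    """Direct evaluation of the recursion (the O(n^2 N^2) reference form).

    Identical objective and tie policy to :func:`segment`; used to verify
    the accelerated solver.
    """
    w = scoring.position_scores
    if w is None:
        raise ValueError("position_scores not filled")
    if n is None:
        n = w.shape[0]
    if n == 0:
        return Segmentation(n=0, segments=[], score=0.0)
    w = w[:n]
    K1 = w.shape[1]
    cs = np.zeros((n + 1, K1))
    np.cumsum(w, axis=0, out=cs[1:])
    pen = np.full(K1, scoring.M)
    pen[0] = scoring.penalty0
    bonus = np.zeros(K1)
    bonus[0] = scoring.nuisance_bonus

    S = np.full((n + 1, K1), -np.inf)
    S[0] = scoring.M
    bp = np.zeros((n + 1, K1, 2), dtype=np.int64)
    for k in range(1, n + 1):
        for alpha in range(K1):
            # all (i, beta) candidates evaluated directly; ties resolved to
            # the smallest i, then the smallest beta (first occurrence)
            sval = cs[k, alpha] - cs[:k, alpha]  # s(i, k, alpha), i = 1..k
            cand = S[:k, :] + sval[:, None] + bonus[alpha] - pen[alpha]
            cand[:, alpha] = -np.inf
            flat = int(np.argmax(cand))
            i0, beta = divmod(flat, K1)
            S[k, alpha] = cand[i0, beta]
            bp[k, alpha] = (i0 + 1, beta)
    alpha = int(np.argmax(S[n]))
    best = float(S[n, alpha])
    segs: list[Segment] = []
    k = n
    while k > 0:
        i, beta = int(bp[k, alpha, 0]), int(bp[k, alpha, 1])
        segs.append(Segment(i, k, cluster=alpha))
        k = i - 1
        alpha = beta
    segs.reverse()
    out = Segmentation(n=n, segments=segs, score=best)
    _interval_scores(scoring, out)
    return out


def chunk_and_segment(
    scoring: ScoringModel,
    n: Optional[int] = None,
    chunk_size: int = 20000,
    overlap: int = 2000,
) -> Segmentation:
    """Segment overlapping chunks independently and stitch by midpoint rule.

    Each chunk owns the half-open window reaching to the midpoints of its
    overlaps with the neighbours; breakpoints are kept from the owning
    chunk, so every breakpoint is retained exactly once and segments far
    from chunk borders reproduce the whole-input segmentation.  The caller
    is responsible for choosing ``overlap`` at least as large as the
    expected maximum segment length.
    """
    w = scoring.position_scores
    if w is None:
        raise ValueError("position_scores not filled")
    if n is None:
        n = w.shape[0]
    if chunk_size <= overlap:
        raise ValueError("chunk_size must exceed overlap")
    if chunk_size <= 2 * overlap:
        raise ValueError("chunk_size must exceed 2 * overlap")
    if n <= chunk_size:
        return segment(scoring, n)

    step = chunk_size - overlap
    starts = list(range(1, n - overlap, step))
    chunks = [(a, min(a + chunk_size - 1, n)) for a in starts]
    if chunks[-1][1] < n:
        chunks.append((n - chunk_size + 1, n))

    # ownership windows: split each overlap at its midpoint
    own: list[tuple[int, int]] = []
    prev_end = 0
    for c, (a, b) in enumerate(chunks):
        if c == len(chunks) - 1:
            hi = n
        else:
            na = chunks[c + 1][0]
            hi = (na + b) // 2
        own.append((prev_end + 1, hi))
        prev_end = hi

    pieces: list[tuple[int, int, int]] = []  # (start, end, cluster) genomic in [1, n]
    for (a, b), (lo, hi) in zip(chunks, own):
        sub = ScoringModel(
            function=scoring.function,
            a=scoring.a,
            epsilon=scoring.epsilon,
            nu=scoring.nu,
            M=scoring.M,
            M0=scoring.M0,
            nuisance_mode=scoring.nuisance_mode,
            position_scores=w[a - 1 : b],
        )
        segn = segment(sub)
        for s in segn.segments:
            gs, ge = s.start + a - 1, s.end + a - 1
            cs_, ce = max(gs, lo), min(ge, hi)
            if cs_ <= ce:
                pieces.append((cs_, ce, s.cluster))
    # merge adjacent pieces with the same cluster (window joins)
    merged: list[Segment] = []
    for st, en, cl in pieces:
        if merged and merged[-1].cluster == cl and merged[-1].end + 1 == st:
            merged[-1].end = en
        else:
            merged.append(Segment(st, en, cluster=cl))
    out = Segmentation(n=n, segments=merged, score=0.0)
    out.score = objective_score(
        ScoringModel(
            function=scoring.function,
            a=scoring.a,
            epsilon=scoring.epsilon,
            nu=scoring.nu,
            M=scoring.M,
            M0=scoring.M0,
            nuisance_mode=scoring.nuisance_mode,
            position_scores=w[:n],
        ),
        out,
    )
    _interval_scores(scoring, out)
    return out
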
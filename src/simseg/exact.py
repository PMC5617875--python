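"""Exact dynamic-programming segmentation in a similarity space.

The signal lives in a *similarity space*: a set with a symmetric similarity
function sigma for which self-similarity dominates,

    (s0)  sigma(u, u) >= 0
    (s1)  sigma(u, v) == sigma(v, u)
    (s2)  sigma(u, u) >= sigma(u, v)

No triangle inequality or identity of indiscernibles is required.  An
interval ``[i, k]`` is scored either by the *average* similarity of each
member to the whole interval (sigma_a) or by the total similarity to the
interval's *medoid* (sigma_m), the element maximizing total similarity to
all members.  The optimal segmentation into a fixed number of intervals, or
under a per-jump penalty M, is found by dynamic programming; a brute-force
enumerator over all breakpoint sets serves as the test oracle.

This solver is quadratic/cubic in n and intended as the exact reference for
modest n; genome-scale inputs go through :mod:`simseg.clusterseg`.
"""

from __future__ import annotations

from typing import Callable, Literal, Optional, Union

import numpy as np

from .segments import Segment, Segmentation, segmentation_from_breakpoints

Mode = Literal["average", "medoid"]

_VALIDATE_SAMPLES = 64  # pairs spot-checked when sigma is a callable


class SimilaritySpace:
    """n points with a dense pairwise similarity matrix.

    Parameters
    ----------
    sim : (n, n) array or callable ``sigma(u, v)`` on 1-based indices
    n : required when ``sim`` is a callable
    validate : check axioms (s0)-(s2); matrices are checked exhaustively,
        callables on a sample of pairs.
    """

    def __init__(
        self,
        sim: Union[np.ndarray, Callable[[int, int], float]],
        n: Optional[int] = None,
        validate: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        if callable(sim):
            if n is None:
                raise ValueError("n is required for callable similarities")
            mat = np.empty((n, n), dtype=float)
            for u in range(n):
                for v in range(u, n):
                    mat[u, v] = mat[v, u] = float(sim(u + 1, v + 1))
            if validate:
                self._spot_check(sim, n, rng)
        else:
            mat = np.asarray(sim, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError("similarity matrix must be square")
            if n is not None and n != mat.shape[0]:
                raise ValueError("n does not match matrix shape")
        if not np.all(np.isfinite(mat)):
            raise ValueError("similarities must be finite")
        if validate:
            d = np.diag(mat)
            if np.any(d < 0):
                raise ValueError("axiom (s0) violated: sigma(u,u) < 0")
            if not np.allclose(mat, mat.T, atol=1e-12):
                raise ValueError("axiom (s1) violated: sigma not symmetric")
            if np.any(mat > d[:, None] + 1e-12):
                raise ValueError("axiom (s2) violated: sigma(u,v) > sigma(u,u)")
        self.sim = mat
        self.n = mat.shape[0]
        # prefix sums for fast interval scores
        self._P2 = np.zeros((self.n + 1, self.n + 1))  # 2-D prefix over sim
        self._P2[1:, 1:] = mat.cumsum(axis=0).cumsum(axis=1)
        self._colP = np.zeros((self.n + 1, self.n))  # colP[k, m] = sum sim[:k, m]
        self._colP[1:] = mat.cumsum(axis=0)

    @staticmethod
    def _spot_check(sim: Callable, n: int, rng: Optional[np.random.Generator]) -> None:
        rng = rng or np.random.default_rng(0)
        us = rng.integers(1, n + 1, size=_VALIDATE_SAMPLES)
        vs = rng.integers(1, n + 1, size=_VALIDATE_SAMPLES)
        for u, v in zip(us.tolist(), vs.tolist()):
            suv, svu = float(sim(u, v)), float(sim(v, u))
            suu = float(sim(u, u))
            if suu < 0:
                raise ValueError("axiom (s0) violated on sampled pair")
            if abs(suv - svu) > 1e-12:
                raise ValueError("axiom (s1) violated on sampled pair")
            if suv > suu + 1e-12:
                raise ValueError("axiom (s2) violated on sampled pair")


def interval_score(space: SimilaritySpace, i: int, k: int, mode: Mode = "average") -> float:
    """Score f([i, k]) under average (sigma_a) or medoid (sigma_m) similarity.

    average:  f = sum_u (1/|I|) sum_v sigma(u, v)
    medoid:   f = max_{m in I} sum_v sigma(v, m)   (tie -> smallest index)
    """
    if not (1 <= i <= k <= space.n):
        raise ValueError(f"invalid interval [{i}, {k}] for n={space.n}")
    if mode == "average":
        block = (
            space._P2[k, k]
            - space._P2[i - 1, k]
            - space._P2[k, i - 1]
            + space._P2[i - 1, i - 1]
        )
        return float(block / (k - i + 1))
    if mode == "medoid":
        totals = space._colP[k, i - 1 : k] - space._colP[i - 1, i - 1 : k]
        return float(totals.max())
    raise ValueError(f"unknown mode {mode!r}")


def interval_medoid(space: SimilaritySpace, i: int, k: int) -> int:
    """1-based index of the medoid of [i, k]; ties -> smallest index."""
    if not (1 <= i <= k <= space.n):
        raise ValueError(f"invalid interval [{i}, {k}]")
    totals = space._colP[k, i - 1 : k] - space._colP[i - 1, i - 1 : k]
    return i + int(np.argmax(totals))


def score_matrix(space: SimilaritySpace, mode: Mode) -> np.ndarray:
    """f[i-1, k-1] = interval score of [i, k] for all 1 <= i <= k <= n."""
    n = space.n
    f = np.full((n, n), -np.inf)
    if mode == "average":
        lens = np.arange(1, n + 1, dtype=float)
        for i in range(1, n + 1):
            ks = np.arange(i, n + 1)
            block = (
                space._P2[ks, ks]
                - space._P2[i - 1, ks]
                - space._P2[ks, i - 1]
                + space._P2[i - 1, i - 1]
            )
            f[i - 1, i - 1 :] = block / lens[: n - i + 1]
    elif mode == "medoid":
        for i in range(1, n + 1):
            # totals[k - i, m - i] = sum_{v in [i,k]} sigma(v, m)
            totals = space._colP[i:, i - 1 :] - space._colP[i - 1, i - 1 :]
            # medoid candidates m are restricted to [i, k]
            for k in range(i, n + 1):
                f[i - 1, k - 1] = totals[k - i, : k - i + 1].max()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return f


def _segment_scores(f: np.ndarray, bounds: list[int]) -> list[float]:
    return [float(f[bounds[h] , bounds[h + 1] - 1]) for h in range(len(bounds) - 1)]


def _fixed_tables(f: np.ndarray, lmax: int) -> np.ndarray:
    """S[h, k] = best score of segmenting [1, k] into exactly h intervals.

    Ties in the inner max are broken toward the *later* breakpoint.
    S has shape (lmax+1, n+1); S[h, k] = -inf where k < h.
    """
    n = f.shape[0]
    S = np.full((lmax + 1, n + 1), -np.inf)
    S[0, 0] = 0.0
    for h in range(1, lmax + 1):
        for k in range(h, n + 1):
            js = np.arange(h - 1, k)
            vals = S[h - 1, js] + f[js, k - 1]
            S[h, k] = vals.max()
    return S


def _backtrace_fixed(f: np.ndarray, S: np.ndarray, ell: int, n: int) -> list[int]:
    """Recover breakpoints for S[ell, n]; ties -> later breakpoint."""
    bounds = [n]
    k = n
    for h in range(ell, 0, -1):
        if h == 1:
            bounds.append(0)
            break
        js = np.arange(h - 1, k)
        vals = S[h - 1, js] + f[js, k - 1]
        best = vals.max()
        # latest j attaining the max
        j = int(js[np.nonzero(np.isclose(vals, best, rtol=0, atol=0))[0][-1]])
        bounds.append(j)
        k = j
    return bounds[::-1]


def solve_fixed_segments(space: SimilaritySpace, ell: int, mode: Mode = "average") -> Segmentation:
    """Optimal segmentation into exactly ``ell`` non-empty intervals."""
    n = space.n
    if not (1 <= ell <= n):
        raise ValueError(f"number of segments {ell} outside [1, {n}]")
    f = score_matrix(space, mode)
    S = _fixed_tables(f, ell)
    bounds = _backtrace_fixed(f, S, ell, n)
    per = _segment_scores(f, bounds)
    segs = [
        Segment(bounds[h] + 1, bounds[h + 1], score=per[h])
        for h in range(len(bounds) - 1)
    ]
    return Segmentation(n=n, segments=segs, score=float(S[ell, n]))


def solve_penalized(space: SimilaritySpace, M: float, mode: Mode = "average") -> Segmentation:
    """Maximize sum_h f(I_h) - M (ell - 1) over all ell; ties -> fewer intervals."""
    if M < 0:
        raise ValueError("penalty M must be >= 0")
    n = space.n
    f = score_matrix(space, mode)
    S = _fixed_tables(f, n)
    totals = S[1 : n + 1, n] - M * np.arange(n, dtype=float)
    best = totals.max()
    ell = 1 + int(np.nonzero(totals == best)[0][0])  # smallest ell on ties
    bounds = _backtrace_fixed(f, S, ell, n)
    per = _segment_scores(f, bounds)
    segs = [
        Segment(bounds[h] + 1, bounds[h + 1], score=per[h])
        for h in range(len(bounds) - 1)
    ]
    return Segmentation(n=n, segments=segs, score=float(best))


_BRUTE_LIMIT = 16


def brute_force_segment(
    space: SimilaritySpace,
    mode: Mode = "average",
    ell: Optional[int] = None,
    M: Optional[float] = None,
    return_cooptimal: bool = False,
):
    """Exhaustive test oracle over all 2^(n-1) breakpoint sets (n <= 16).

    Exactly one of ``ell`` (fixed number of segments) or ``M`` (jump
    penalty) must be given.  With ``return_cooptimal`` the full set of
    optimal breakpoint tuples is returned alongside the segmentation.
    """
    n = space.n
    if n > _BRUTE_LIMIT:
        raise ValueError(f"brute force refused for n={n} > {_BRUTE_LIMIT}")
    if (ell is None) == (M is None):
        raise ValueError("give exactly one of ell or M")
    f = score_matrix(space, mode)
    best_score = -np.inf
    best_bps: tuple[int, ...] = ()
    cooptimal: list[tuple[int, ...]] = []
    for mask in range(1 << (n - 1)):
        bps = tuple(j + 1 for j in range(n - 1) if mask >> j & 1)
        if ell is not None and len(bps) != ell - 1:
            continue
        bounds = [0, *bps, n]
        total = sum(f[bounds[h], bounds[h + 1] - 1] for h in range(len(bounds) - 1))
        if M is not None:
            total -= M * len(bps)
        if total > best_score + 1e-12:
            best_score = total
            best_bps = bps
            cooptimal = [bps]
        elif abs(total - best_score) <= 1e-12:
            cooptimal.append(bps)
    seg = segmentation_from_breakpoints(n, list(best_bps), score=float(best_score))
    if return_cooptimal:
        return seg, cooptimal
    return seg
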
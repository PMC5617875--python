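"""Coverage-based pre-segmentation at extended non-expressed regions.

Long stretches without any read signal are safe anchors at which a
chromosome can be split into independent pieces before the (quadratic-in-n
at worst) segmentation is run.  The heuristic works on the *presence*
signal n_i — the number of time points with any coverage at position i —
and therefore depends only on the zero/non-zero pattern of the counts:

1. smooth n_i with a wide centered moving average (window ``avg``);
2. candidate gaps are maximal runs of length >= ``min_gap_len`` where the
   smoothed presence stays at or below ``minrd`` time points;
3. pre-segments are the complements of the gaps;
4. each pre-segment boundary is moved to the point where a *narrow*
   moving average (window ``favg``) of n_i, facing outward from the
   pre-segment, first reaches 0 — extending over trailing weakly
   expressed positions and trimming enclosed all-zero margins, so the
   final boundary sits at the last position with any signal whenever the
   adjacent zero run is longer than ``favg``;
5. pre-segments shorter than ``minsg`` are fused with the neighbour across
   the shorter inter-segment (ties to the left);
6. nothing extends or fuses across a chromosome end.

Pre-segments and inter-segments partition the chromosome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import CoverageTrack

Interval = tuple[int, int]  # 1-based inclusive genomic coordinates


@dataclass
class PresegParams:
    avg: int = 1000  # wide moving-average window (nt)
    favg: int = 100  # narrow window for boundary placement (nt)
    minrd: int = 8  # expressed-time-point threshold (counts, of d)
    minsg: int = 1000  # minimum pre-segment length (nt)
    min_gap_len: int = 1000  # required low-signal run length (nt)

    def __post_init__(self) -> None:
        if self.favg > self.avg:
            raise ValueError("favg must be <= avg")
        if self.minrd <= 0:
            raise ValueError("minrd must be positive")


def expression_presence(track: CoverageTrack) -> np.ndarray:
    """n_i = number of time points with count > 0 at each position."""
    return (track.counts > 0).sum(axis=1).astype(int)


def centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the ends."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    kernel = np.ones(min(window, len(x)))
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based half-open (start, stop)."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    stops = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _outward_averages(n_i: np.ndarray, favg: int) -> tuple[np.ndarray, np.ndarray]:
    """right[i] = mean n over [i, i+favg); left[i] = mean over (i-favg, i]."""
    L = len(n_i)
    win = min(favg, L)
    c = np.concatenate([[0.0], np.cumsum(n_i, dtype=float)])
    idx = np.arange(L)
    hi = np.minimum(idx + win, L)
    right = (c[hi] - c[idx]) / (hi - idx)
    lo = np.maximum(idx + 1 - win, 0)
    left = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    return left, right


def presegment(
    track: CoverageTrack, params: PresegParams | None = None
) -> tuple[list[Interval], list[Interval]]:
    """Split a track into (pre-segments, inter-segments), both 1-based
    inclusive genomic intervals that together tile the track exactly."""
    params = params or PresegParams()
    n_i = expression_presence(track)
    L = len(n_i)

    if not n_i.any():
        return [], [(track.start, track.end)]

    ntilde = centered_moving_average(n_i, params.avg)
    gap_mask = ntilde <= params.minrd
    gaps = [(a, b) for a, b in _runs(gap_mask) if b - a >= params.min_gap_len]

    # pre-segments = complement of the gaps (0-based half-open)
    presegs: list[list[int]] = []
    pos = 0
    for a, b in gaps:
        if a > pos:
            presegs.append([pos, a])
        pos = b
    if pos < L:
        presegs.append([pos, L])
    if not presegs:
        return [], [(track.start, track.end)]

    # boundary placement with the outward-facing narrow average
    left_avg, right_avg = _outward_averages(n_i, params.favg)
    adjusted: list[list[int]] = []
    for a, b in presegs:
        lo_lim = adjusted[-1][1] if adjusted else 0
        # right boundary: last index r (exclusive bound r+1) before the
        # first outward zero of the narrow average
        r = b - 1
        if right_avg[r] == 0:
            while r > a and right_avg[r] == 0:
                r -= 1
        else:
            while r + 1 < L and right_avg[r + 1] > 0:
                r += 1
        # left boundary, symmetric
        l = a
        if left_avg[l] == 0:
            while l < r and left_avg[l] == 0:
                l += 1
        else:
            while l - 1 >= lo_lim and left_avg[l - 1] > 0:
                l -= 1
        if r < l or not n_i[l : r + 1].any():
            continue  # vanished: all-zero pre-segment becomes inter-segment
        if adjusted and l <= adjusted[-1][1]:
            adjusted[-1][1] = max(adjusted[-1][1], r + 1)
        else:
            adjusted.append([l, r + 1])
    presegs = adjusted
    if not presegs:
        return [], [(track.start, track.end)]

    # fuse short pre-segments with the neighbour across the shorter gap
    def length(seg: list[int]) -> int:
        return seg[1] - seg[0]

    while len(presegs) > 1:
        short = [i for i, s in enumerate(presegs) if length(s) < params.minsg]
        if not short:
            break
        i = min(short, key=lambda i: (length(presegs[i]), i))
        if i == 0:
            j = 1
        elif i == len(presegs) - 1:
            j = i - 1
        else:
            gap_left = presegs[i][0] - presegs[i - 1][1]
            gap_right = presegs[i + 1][0] - presegs[i][1]
            j = i - 1 if gap_left <= gap_right else i + 1
        lo, hi = min(i, j), max(i, j)
        fused = [presegs[lo][0], presegs[hi][1]]
        presegs[lo : hi + 1] = [fused]

    # inter-segments = complement (0-based half-open), then lift to genomic
    inters: list[Interval] = []
    pos = 0
    out: list[Interval] = []
    for a, b in presegs:
        if a > pos:
            inters.append((track.start + pos, track.start + a - 1))
        out.append((track.start + a, track.start + b - 1))
        pos = b
    if pos < L:
        inters.append((track.start + pos, track.start + L - 1))
    return out, inters
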
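"""Segmentation container shared by the exact and the cluster-based solvers.

Coordinates are 1-based inclusive over the index range ``[1, n]`` of the
segmented signal.  Genomic placement (chromosome, strand, offset) is attached
only when a segmentation is lifted back onto a coverage track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence


@dataclass
class Segment:
    """One interval of a segmentation, 1-based inclusive."""

    start: int
    end: int
    cluster: Optional[int] = None  # 0 = nuisance, >=1 real cluster
    score: Optional[float] = None

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end}]")


@dataclass
class Segmentation:
    """An ordered tiling of ``[1, n]`` into non-empty consecutive intervals."""

    n: int
    segments: list[Segment] = field(default_factory=list)
    score: float = 0.0
    chromosome: Optional[str] = None
    strand: Optional[str] = None
    offset: int = 0  # genomic coordinate of index 1 minus 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n == 0:
            if self.segments:
                raise ValueError("n=0 segmentation must be empty")
            return
        if not self.segments:
            raise ValueError("non-empty range requires at least one segment")
        pos = 1
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError(
                    f"segments do not tile [1,{self.n}]: expected start {pos}, "
                    f"got {seg.start}"
                )
            pos = seg.end + 1
        if pos != self.n + 1:
            raise ValueError(f"segments end at {pos - 1}, expected {self.n}")

    @property
    def breakpoints(self) -> list[int]:
        """Indices j such that a segment ends at j < n."""
        return [seg.end for seg in self.segments[:-1]]

    @property
    def clusters(self) -> list[Optional[int]]:
        return [seg.cluster for seg in self.segments]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def shifted(self, offset: int) -> "Segmentation":
        """Copy with genomic offset attached (does not change indices)."""
        return Segmentation(
            n=self.n,
            segments=[Segment(s.start, s.end, s.cluster, s.score) for s in self.segments],
            score=self.score,
            chromosome=self.chromosome,
            strand=self.strand,
            offset=offset,
        )

    def genomic_intervals(self) -> list[tuple[int, int, Optional[int]]]:
        """(start, end, cluster) in 1-based inclusive genomic coordinates."""
        return [
            (s.start + self.offset, s.end + self.offset, s.cluster)
            for s in self.segments
        ]


def segmentation_from_breakpoints(
    n: int,
    breakpoints: Sequence[int],
    clusters: Optional[Sequence[Optional[int]]] = None,
    score: float = 0.0,
) -> Segmentation:
    """Build a segmentation from breakpoints (segment ends strictly < n)."""
    bps = sorted(breakpoints)
    if any(b < 1 or b >= n for b in bps):
        raise ValueError("breakpoints must lie in [1, n)")
    bounds = [0] + list(bps) + [n]
    segs = []
    for h in range(len(bounds) - 1):
        cl = clusters[h] if clusters is not None else None
        segs.append(Segment(bounds[h] + 1, bounds[h + 1], cl))
    return Segmentation(n=n, segments=segs, score=score)
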
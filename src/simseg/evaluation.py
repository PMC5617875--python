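"""Annotation-recovery statistics for a segmentation.

Given query segments Q (the segmentation under test) and target intervals T
(e.g. experimentally defined ORF transcripts), each target is matched to
its *best hit*: the overlapping query with the highest Jaccard index
J = |Q n T| / |Q u T|.  Per target the number of overlapping queries
(n_hits), the best-hit J and the best-hit length ratio R = |Q| / |T| are
recorded; globally:

* ``J_tot``  — micro-averaged total Jaccard of the best-hit pairs,
  sum of intersections / sum of unions (the macro average, the mean of
  per-target J, is reported alongside);
* ``R_short`` — fraction of hit targets with R <= 0.8 (over-fragmentation);
* ``R_long``  — fraction of hit targets with R <= 1.2;
* ``n_hits_mean`` — average number of query hits per target.

Intervals are 1-based inclusive; overlaps are only counted on the same
chromosome and strand.  Targets without any overlapping query have
n_hits = 0, J = 0 and an undefined R (excluded from the R fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    name: str = ""
    cluster: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RecoveryStats:
    per_target: pd.DataFrame  # name, chrom, strand, n_hits, J, R
    J_tot: float  # micro-averaged best-hit Jaccard
    J_mean: float  # macro average (mean per-target J)
    R_short: float
    R_long: float
    n_hits_mean: float
    n_targets: int
    extras: dict = field(default_factory=dict)


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    """Positionwise Jaccard index of two 1-based inclusive intervals.

    Intervals on different chromosomes or strands do not overlap by
    contract and score 0.
    """
    if a.chromosome != b.chromosome or a.strand != b.strand:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    union = len(a) + len(b) - inter
    return inter / union


def recovery_stats(
    queries: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> RecoveryStats:
    """Best-hit recovery of ``targets`` by ``queries``.

    Best-hit ties prefer the larger J, then the smaller query start.
    Empty queries produce all-zero statistics; empty targets are invalid.
    """
    if not targets:
        raise ValueError("recovery_stats requires at least one target")
    rows = []
    inter_sum = 0
    union_sum = 0
    for t in targets:
        tlen = len(t)
        n_hits = 0
        best = None  # (J, -query start, inter, qlen)
        for q in queries:
            if q.chromosome != t.chromosome or q.strand != t.strand:
                continue
            inter = min(q.end, t.end) - max(q.start, t.start) + 1
            if inter <= 0:
                continue
            n_hits += 1
            J = inter / (len(q) + tlen - inter)
            key = (J, -q.start)
            if best is None or key > best[0]:
                best = (key, inter, len(q))
        if best is None:
            # no best-hit pair: the target contributes to neither sum
            rows.append((t.name, t.chromosome, t.strand, 0, 0.0, np.nan))
        else:
            (J, _), inter, qlen = best
            rows.append((t.name, t.chromosome, t.strand, n_hits, J, qlen / tlen))
            inter_sum += inter
            union_sum += qlen + tlen - inter
    per = pd.DataFrame(
        rows, columns=["name", "chromosome", "strand", "n_hits", "J", "R"]
    )
    hit = per["n_hits"] > 0
    n_hit = int(hit.sum())
    return RecoveryStats(
        per_target=per,
        J_tot=float(inter_sum / union_sum) if union_sum else 0.0,
        J_mean=float(per["J"].mean()),
        R_short=float((per.loc[hit, "R"] <= 0.8).sum() / n_hit) if n_hit else 0.0,
        R_long=float((per.loc[hit, "R"] <= 1.2).sum() / n_hit) if n_hit else 0.0,
        n_hits_mean=float(per["n_hits"].mean()),
        n_targets=len(targets),
    )


def scan_summary(entries: Sequence[tuple[dict, RecoveryStats]]) -> pd.DataFrame:
    """One row per parameter set with its four global recovery statistics."""
    if not entries:
        raise ValueError("scan_summary requires at least one entry")
    rows = []
    for params, stats in entries:
        row = dict(params)
        row.update(
            J_tot=stats.J_tot,
            J_mean=stats.J_mean,
            n_hits_mean=stats.n_hits_mean,
            R_short=stats.R_short,
            R_long=stats.R_long,
        )
        rows.append(row)
    return pd.DataFrame(rows)
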
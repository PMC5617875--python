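"""Per-position DFT features of coverage time series.

Each genomic position carries a d-point read-count time series.  For
oscillatory transcriptomes the temporal *pattern* (phase and relative
amplitude), not the coverage level, is what distinguishes transcripts, so
positions are represented by selected components of the discrete Fourier
transform of their series:

* the transform is normalized by 1/d so that component 1 (DC) equals the
  temporal mean;
* component 1 is kept as a single real column, optionally compressed by
  arcsinh (``dc_trafo``) so mean expression informs but does not dominate
  the similarity;
* each retained non-DC component contributes its real and imaginary part;
  with ``use_snr`` its amplitude is divided by the position's mean non-DC
  amplitude (a per-position signal-to-noise normalization that makes the
  features scale-invariant) while the phase is untouched;
* positions with an all-zero raw series are flagged as *nuisance*
  (non-expressed) and get a zero feature row.

Positions are processed independently; there is no smoothing along the
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class CoverageTrack:
    """Strand-specific per-nucleotide read counts, one column per time point.

    ``start`` is the 1-based genomic coordinate of the first row; rows are
    consecutive positions with no gaps.
    """

    chromosome: str
    strand: str
    start: int
    counts: np.ndarray  # (n, d), non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D position x time matrix")
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 2:
            raise ValueError("counts needs >= 1 row and >= 2 time points")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def d(self) -> int:
        return self.counts.shape[1]

    @property
    def end(self) -> int:
        """1-based inclusive genomic coordinate of the last row."""
        return self.start + self.n - 1

    def slice(self, start: int, end: int) -> "CoverageTrack":
        """Sub-track over genomic positions [start, end] (1-based inclusive)."""
        if start < self.start or end > self.end or start > end:
            raise ValueError(f"slice [{start}, {end}] outside track extent")
        a = start - self.start
        return CoverageTrack(self.chromosome, self.strand, start, self.counts[a : a + end - start + 1])


@dataclass
class DFTSettings:
    """Knobs of the feature transform, named after the tool's vocabulary."""

    trafo: str = "raw"  # {"raw", "ash"}: transform applied before the DFT
    dft_range: Sequence[int] = tuple(range(1, 8))  # 1-based components, 1 = DC
    dc_trafo: str = "ash"  # {"raw", "ash"}: transform of the DC column
    use_snr: bool = True  # per-position amplitude normalization
    dc_weight: float = 1.0  # multiplicative weight of the DC column

    def __post_init__(self) -> None:
        if self.trafo not in ("raw", "ash"):
            raise ValueError(f"trafo must be raw|ash, got {self.trafo!r}")
        if self.dc_trafo not in ("raw", "ash"):
            raise ValueError(f"dc_trafo must be raw|ash, got {self.dc_trafo!r}")
        self.dft_range = tuple(int(c) for c in self.dft_range)
        if any(c < 1 for c in self.dft_range):
            raise ValueError("dft_range components are 1-based (1 = DC)")


@dataclass
class ProcessedSeries:
    """DFT-derived feature rows plus the non-expressed (nuisance) flag."""

    features: np.ndarray  # (n, m)
    nuisance_flag: np.ndarray  # (n,) bool, True = all-zero raw series
    settings: DFTSettings = field(default_factory=DFTSettings)

    @property
    def n(self) -> int:
        return self.features.shape[0]


def arcsinh_transform(values) -> np.ndarray:
    """Elementwise ash(x) = ln(x + sqrt(x^2 + 1)); order-preserving, ash(0)=0."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("arcsinh_transform requires finite input")
    return np.arcsinh(arr)


def dft_features(track: CoverageTrack, settings: DFTSettings | None = None) -> ProcessedSeries:
    """Compute per-position DFT feature rows for a coverage track.

    Feature layout: ``[DC?] + [Re(c), Im(c) for c in retained non-DC]`` in
    ascending component order.  The DC column is present iff component 1 is
    in ``dft_range``.
    """
    settings = settings or DFTSettings()
    counts = track.counts
    d = track.d
    if d < 2:
        raise ValueError("need at least 2 time points")
    nyquist = d // 2 + 1
    if any(c > nyquist for c in settings.dft_range):
        raise ValueError(
            f"dft_range contains components above the Nyquist index {nyquist}"
        )

    nuisance = ~counts.any(axis=1)

    x = arcsinh_transform(counts) if settings.trafo == "ash" else counts
    F = np.fft.rfft(x, axis=1) / d  # component c (1-based) = F[:, c-1]

    nondc = sorted(c for c in settings.dft_range if c != 1)
    cols: list[np.ndarray] = []

    if 1 in settings.dft_range:
        # DC as total signal over the cycle; ash keeps it informative without
        # letting the expression level dominate the correlation.
        total = F[:, 0].real * d
        dc = arcsinh_transform(total) if settings.dc_trafo == "ash" else total / d
        cols.append(settings.dc_weight * dc)

    if nondc:
        comps = F[:, [c - 1 for c in nondc]]
        if settings.use_snr:
            all_amp = np.abs(F[:, 1:])  # every non-DC component up to Nyquist
            mean_amp = all_amp.mean(axis=1)
            scale = np.ones_like(mean_amp)
            np.divide(1.0, mean_amp, out=scale, where=mean_amp > 0)
            comps = comps * scale[:, None]
        for j in range(comps.shape[1]):
            cols.append(comps[:, j].real)
            cols.append(comps[:, j].imag)

    if not cols:
        raise ValueError("dft_range selected no components")
    features = np.column_stack(cols)
    features[nuisance] = 0.0
    return ProcessedSeries(features=features, nuisance_flag=nuisance, settings=settings)
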
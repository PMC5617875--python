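"""Synthetic oscillatory-transcriptome coverage with known truth.

Emulates a compact genome densely packed with transcripts whose temporal
profiles are phase-shifted oscillations over a non-integer number of
cycles (default 2.5, deliberately off-bin so that spectral leakage into
neighbouring DFT components is exercised), sampled at d time points
(default 24).  Expected coverage of a position p inside transcript tau at
time t is

    lambda(p, t) = edge(p) * [ baseline + amplitude * (1 + cos(2 pi * cycles * t / d - phase)) ]

where ``edge`` ramps linearly from 0 to 1 over ``end_gradient_length`` nt
at both transcript ends (coverage gradients at transcript boundaries).
Overlapping same-strand transcripts sum; reverse-strand transcripts cover
the reverse track only; positions outside all transcripts are exactly 0.
Counts are drawn per position and time point from a Poisson or negative
binomial with that mean, or taken as the exact expectation with noise off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .evaluation import GenomicInterval
from .timeseries import CoverageTrack

NoiseFamily = Literal["none", "poisson", "negative_binomial"]


@dataclass
class Transcript:
    chromosome: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    phase: float  # radians in [0, 2 pi)
    amplitude: float
    baseline: float
    end_gradient_length: int = 100
    name: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("transcript end before start")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be >= 0")
        if not (0 <= self.phase < 2 * np.pi):
            raise ValueError("phase must lie in [0, 2 pi)")


@dataclass
class SyntheticGenome:
    chromosomes: list[tuple[str, int]]
    transcripts: list[Transcript]
    noise: NoiseFamily = "poisson"
    dispersion: float = 10.0  # negative-binomial size parameter r
    d: int = 24
    cycles: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for tr in self.transcripts:
            if tr.chromosome not in lengths:
                raise ValueError(f"unknown chromosome {tr.chromosome!r}")
            if tr.start < 1 or tr.end > lengths[tr.chromosome]:
                raise ValueError(f"transcript {tr.name!r} outside its chromosome")

    def manifest(self) -> dict:
        """All generator parameters, JSON-serializable (reproducibility)."""
        return {
            "chromosomes": [list(c) for c in self.chromosomes],
            "transcripts": [
                {
                    "chromosome": t.chromosome,
                    "strand": t.strand,
                    "start": t.start,
                    "end": t.end,
                    "phase": t.phase,
                    "amplitude": t.amplitude,
                    "baseline": t.baseline,
                    "end_gradient_length": t.end_gradient_length,
                    "name": t.name,
                }
                for t in self.transcripts
            ],
            "noise": self.noise,
            "dispersion": self.dispersion,
            "d": self.d,
            "cycles": self.cycles,
            "seed": self.seed,
        }


def _edge_profile(length: int, gradient: int) -> np.ndarray:
    """Linear 0->1 ramp over ``gradient`` nt at both ends, 1 in the middle."""
    p = np.arange(1, length + 1, dtype=float)
    if gradient <= 0:
        return np.ones(length)
    up = p / gradient
    down = (length - p + 1) / gradient
    return np.minimum(1.0, np.minimum(up, down))


def expected_coverage(genome: SyntheticGenome) -> dict[tuple[str, str], np.ndarray]:
    """Noise-free expectation per (chromosome, strand), shape (length, d)."""
    t = np.arange(genome.d)
    out: dict[tuple[str, str], np.ndarray] = {}
    for name, length in genome.chromosomes:
        for strand in "+-":
            out[(name, strand)] = np.zeros((length, genome.d))
    for tr in genome.transcripts:
        profile = tr.baseline + tr.amplitude * (
            1 + np.cos(2 * np.pi * genome.cycles * t / genome.d - tr.phase)
        )
        edge = _edge_profile(tr.end - tr.start + 1, tr.end_gradient_length)
        out[(tr.chromosome, tr.strand)][tr.start - 1 : tr.end] += np.outer(edge, profile)
    return out


def simulate_coverage(
    genome: SyntheticGenome,
) -> tuple[dict[tuple[str, str], CoverageTrack], list[GenomicInterval]]:
    """Sample coverage tracks and the matching truth intervals.

    Deterministic given ``genome.seed``; positions outside every transcript
    are exactly zero under all noise families.
    """
    rng = np.random.default_rng(genome.seed)
    expect = expected_coverage(genome)
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for key in sorted(expect):  # fixed draw order for determinism
        lam = expect[key]
        if genome.noise == "none":
            counts = lam.copy()
        elif genome.noise == "poisson":
            counts = rng.poisson(lam).astype(float)
        elif genome.noise == "negative_binomial":
            r = genome.dispersion
            p = np.where(lam > 0, r / (r + lam), 1.0)
            counts = rng.negative_binomial(r, p).astype(float)
            counts[lam == 0] = 0.0
        else:
            raise ValueError(f"unknown noise family {genome.noise!r}")
        chrom, strand = key
        tracks[key] = CoverageTrack(chrom, strand, 1, counts)
    truth = [
        GenomicInterval(t.chromosome, t.start, t.end, t.strand, t.name or f"tx{i+1}")
        for i, t in enumerate(genome.transcripts)
    ]
    return tracks, truth


def _desk_transcripts(rng: np.random.Generator) -> list[Transcript]:
    """~60 transcripts in 7 blocks; adjacent transcripts cycle through 4
    phase cohorts so neighbours always differ by pi/2, blocks are separated
    by 2000-nt all-zero gaps, and some blocks carry an antisense overlap."""
    cohorts = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
    transcripts: list[Transcript] = []
    pos = 1001  # leading margin
    idx = 0
    for block in range(7):
        block_start = pos
        for j in range(8):
            length = int(rng.integers(1800, 3201))
            phase = cohorts[(block + j) % 4]
            amp = float(rng.uniform(8, 30))
            base = float(rng.uniform(1.5, 3.0))
            transcripts.append(
                Transcript(
                    "chrS", "+", pos, pos + length - 1, phase, amp, base,
                    end_gradient_length=100, name=f"fwd_b{block}_{j}",
                )
            )
            idx += 1
            pos += length + int(rng.integers(80, 201))  # small within-block gap
        block_end = pos
        if block % 2 == 0:  # antisense transcript overlapping the block
            a_len = int(rng.integers(1800, 2601))
            a_start = block_start + int(rng.integers(500, 1500))
            transcripts.append(
                Transcript(
                    "chrS", "-", a_start, a_start + a_len - 1,
                    cohorts[(block + 2) % 4], float(rng.uniform(8, 25)), 2.0,
                    end_gradient_length=100, name=f"rev_b{block}",
                )
            )
        pos = block_end + 2000  # inter-block all-zero gap
    return transcripts


def standard_fixture(scale: Literal["tiny", "desk"] = "tiny", seed: int = 0) -> SyntheticGenome:
    """Fully specified seeded study genomes.

    ``tiny``: one 5-kb chromosome, 4 transcripts in 2 phase cohorts
    (separated by pi), one antisense overlap, one 600-nt gap.
    ``desk``: one 200-kb chromosome, ~60 transcripts in 4 phase cohorts
    arranged in blocks with 2000-nt all-zero inter-block gaps, Poisson
    noise — the desk-scale stand-in for a densely transcribed genome.
    """
    if scale == "tiny":
        transcripts = [
            Transcript("chrT", "+", 201, 1200, 0.0, 12.0, 2.0, 100, "t1"),
            Transcript("chrT", "+", 1301, 2400, np.pi, 15.0, 2.0, 100, "t2"),
            Transcript("chrT", "+", 3001, 4200, 0.0, 10.0, 2.0, 100, "t3"),
            Transcript("chrT", "-", 1601, 2700, np.pi, 12.0, 2.0, 100, "t4_anti"),
        ]
        return SyntheticGenome(
            chromosomes=[("chrT", 5000)],
            transcripts=transcripts,
            noise="poisson",
            d=24,
            cycles=2.5,
            seed=seed,
        )
    if scale == "desk":
        rng = np.random.default_rng(20170927)  # layout is fixed; seed drives noise
        transcripts = _desk_transcripts(rng)
        last = max(t.end for t in transcripts)
        return SyntheticGenome(
            chromosomes=[("chrS", max(200_000, last + 1000))],
            transcripts=transcripts,
            noise="poisson",
            d=24,
            cycles=2.5,
            seed=seed,
        )
    raise ValueError(f"unknown scale {scale!r}")


def write_manifest(genome: SyntheticGenome, path) -> None:
    with open(path, "w") as fh:
        json.dump(genome.manifest(), fh, indent=1)
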
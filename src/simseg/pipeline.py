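"""End-to-end pipeline: presegment -> process -> cluster -> segment -> evaluate.

Each pre-segment is processed independently with a clustering seed derived
stably from (run seed, chromosome, strand, pre-segment start), so the
merged result does not depend on the order in which pre-segments are
handled and re-runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .clustering import (
    build_similarities,
    kmeans_cluster,
    reassign_nuisance,
)
from .clusterseg import ScoringModel, build_position_scores, chunk_and_segment, segment
from .evaluation import GenomicInterval, RecoveryStats, recovery_stats, scan_summary
from .io import RunConfig, segmentation_to_intervals
from .preseg import PresegParams, presegment
from .segments import Segmentation
from .timeseries import CoverageTrack, DFTSettings, dft_features

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    segments: list[GenomicInterval]
    segment_scores: list[float]
    presegments: dict[tuple[str, str], list[tuple[int, int]]]
    intersegments: dict[tuple[str, str], list[tuple[int, int]]]
    skipped: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    recovery: Optional[RecoveryStats] = None


def derived_seed(seed: int, chromosome: str, strand: str, start: int) -> int:
    """Stable per-pre-segment seed, independent of processing order."""
    key = f"{seed}:{chromosome}:{strand}:{start}".encode()
    return zlib.crc32(key) % 2**31


def _dft_settings(config: RunConfig) -> DFTSettings:
    return DFTSettings(
        trafo=config["trafo"],
        dft_range=config["dft.range"],
        dc_trafo=config["dc.trafo"],
        use_snr=config["use.snr"],
    )


def _scoring(config: RunConfig) -> ScoringModel:
    return ScoringModel(
        function=config["scoring"],
        epsilon=float(config["E"]),
        M=float(config["M"]),
        M0=None if config["Mn"] is None else float(config["Mn"]),
        nu=float(config["nui"]),
        nuisance_mode=config["nuisance.mode"],
    )


def segment_track_piece(
    track: CoverageTrack, config: RunConfig, seed: int
) -> Segmentation:
    """process -> cluster -> score -> segment for one coverage piece."""
    series = dft_features(track, _dft_settings(config))
    model = kmeans_cluster(series, K=int(config["K"]), seed=seed)
    model = build_similarities(series, model)
    model = reassign_nuisance(model, float(config["nui.thresh"]))
    scoring = build_position_scores(model, _scoring(config))
    chunk = int(config["chunk-size"])
    if chunk and track.n > chunk:
        seg = chunk_and_segment(scoring, chunk_size=chunk, overlap=int(config["overlap"]))
    else:
        seg = segment(scoring)
    seg.chromosome = track.chromosome
    seg.strand = track.strand
    seg.offset = track.start - 1
    return seg


def run_pipeline(
    tracks: dict[tuple[str, str], CoverageTrack],
    config: RunConfig,
    targets: Optional[Sequence[GenomicInterval]] = None,
    order: Optional[Sequence[tuple[str, str, int, int]]] = None,
) -> PipelineResult:
    """Run the full pipeline on in-memory coverage tracks.

    ``order`` optionally overrides the processing order of pre-segments
    (chromosome, strand, start, end); the merged output is identical for
    any permutation — each piece derives its own clustering seed and the
    final segment list is sorted by coordinate.
    """
    pparams = PresegParams(
        avg=int(config["avg"]),
        favg=int(config["favg"]),
        minrd=int(config["minrd"]),
        minsg=int(config["minsg"]),
        min_gap_len=int(config["min.gap.len"]),
    )
    presegs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    inters: dict[tuple[str, str], list[tuple[int, int]]] = {}
    jobs: list[tuple[str, str, int, int]] = []
    for key in sorted(tracks):
        ps, its = presegment(tracks[key], pparams)
        presegs[key] = ps
        inters[key] = its
        jobs.extend((key[0], key[1], a, b) for a, b in ps)

    if order is not None:
        wanted = set(jobs)
        if set(order) != wanted:
            raise ValueError("order must be a permutation of the pre-segments")
        jobs = list(order)

    seed = int(config["seed"])
    all_segments: list[GenomicInterval] = []
    all_scores: list[float] = []
    skipped: list[tuple[str, str, int, int, str]] = []
    for chrom, strand, a, b in jobs:
        piece = tracks[(chrom, strand)].slice(a, b)
        piece_seed = derived_seed(seed, chrom, strand, a)
        try:
            seg = segment_track_piece(piece, config, piece_seed)
        except ValueError as exc:
            logger.warning("pre-segment %s%s:%d-%d skipped: %s", chrom, strand, a, b, exc)
            skipped.append((chrom, strand, a, b, str(exc)))
            continue
        ivs, scores = segmentation_to_intervals(seg, include_nuisance=False)
        all_segments.extend(ivs)
        all_scores.extend(scores)

    # canonical order: merged output independent of processing order
    idx = sorted(
        range(len(all_segments)),
        key=lambda i: (
            all_segments[i].chromosome,
            all_segments[i].strand,
            all_segments[i].start,
            all_segments[i].end,
        ),
    )
    all_segments = [all_segments[i] for i in idx]
    all_scores = [all_scores[i] for i in idx]

    recovery = None
    if targets:
        recovery = recovery_stats(all_segments, list(targets))
    return PipelineResult(
        segments=all_segments,
        segment_scores=all_scores,
        presegments=presegs,
        intersegments=inters,
        skipped=skipped,
        recovery=recovery,
    )


def parameter_scan(
    tracks: dict[tuple[str, str], CoverageTrack],
    base_config: RunConfig,
    grid: Sequence[dict],
    targets: Sequence[GenomicInterval],
):
    """Run the pipeline once per parameter set and tabulate recovery."""
    entries = []
    for override in grid:
        params = dict(base_config.params)
        params.update(override)
        cfg = RunConfig(
            params=params,
            input_dir=base_config.input_dir,
            output_dir=base_config.output_dir,
            targets=base_config.targets,
        )
        result = run_pipeline(tracks, cfg, targets=targets)
        entries.append((override, result.recovery))
    return scan_summary(entries)
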
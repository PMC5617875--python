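"""Readers/writers for bedGraph, BED, GFF3, cluster-model bundles and config.

Coordinate conventions are followed bit-exactly: bedGraph and BED are
0-based half-open, GFF3 is 1-based inclusive; internally everything is
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterModel
from .evaluation import GenomicInterval
from .segments import Segmentation
from .timeseries import CoverageTrack


# ---------------------------------------------------------------- bedGraph

def read_bedgraph(
    paths: Sequence[str | Path],
    chrom_lengths: Mapping[str, int],
    chromosome: str,
    strand: str,
) -> CoverageTrack:
    """Read one file per time point into a dense position x time matrix.

    Records are 0-based half-open; absent positions are 0.  Overlapping
    records within one file, or records beyond the chromosome length, are
    errors.
    """
    if chromosome not in chrom_lengths:
        raise ValueError(f"unknown chromosome {chromosome!r}")
    L = chrom_lengths[chromosome]
    counts = np.zeros((L, len(paths)))
    for t, path in enumerate(paths):
        covered = np.zeros(L, dtype=bool)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")[:4]
                if chrom != chromosome:
                    continue
                a, b = int(start), int(end)
                if b > L:
                    raise ValueError(f"{path}: record [{a},{b}) beyond length {L}")
                if a >= b:
                    raise ValueError(f"{path}: empty record [{a},{b})")
                if covered[a:b].any():
                    raise ValueError(f"{path}: overlapping records at [{a},{b})")
                covered[a:b] = True
                counts[a:b, t] = float(value)
    return CoverageTrack(chromosome, strand, 1, counts)


def write_bedgraph(track: CoverageTrack, directory: str | Path, prefix: str = "cov") -> list[Path]:
    """Write one bedGraph per time point (runs of equal value collapsed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tag = "fwd" if track.strand == "+" else "rev"
    out = []
    for t in range(track.d):
        path = directory / f"{prefix}_{tag}_t{t:02d}.bedgraph"
        col = track.counts[:, t]
        with open(path, "w") as fh:
            # run-length encode; zero runs are omitted (absent = 0)
            change = np.nonzero(np.diff(col))[0] + 1
            bounds = np.concatenate([[0], change, [len(col)]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                v = col[a]
                if v != 0:
                    gs = track.start - 1 + a  # 0-based
                    ge = track.start - 1 + b
                    fh.write(f"{track.chromosome}\t{gs}\t{ge}\t{v:g}\n")
        out.append(path)
    return out


# --------------------------------------------------------------------- BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(GenomicInterval(chrom, start + 1, end, strand, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path, scores: Optional[Sequence[float]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            fh.write(
                f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t"
                f"{score:g}\t{iv.strand}\n"
            )


def segmentation_to_intervals(
    seg: Segmentation, include_nuisance: bool = False
) -> tuple[list[GenomicInterval], list[float]]:
    """Per-segment genomic intervals and raw scores (nuisance optional)."""
    ivs, scores = [], []
    for s in seg.segments:
        if s.cluster == 0 and not include_nuisance:
            continue
        name = "nuisance" if s.cluster == 0 else f"cluster_{s.cluster}"
        ivs.append(
            GenomicInterval(
                seg.chromosome or ".", s.start + seg.offset, s.end + seg.offset,
                seg.strand or "+", name, cluster=s.cluster,
            )
        )
        scores.append(0.0 if s.score is None else float(s.score))
    return ivs, scores


def write_segments(
    seg_or_intervals,
    path: str | Path,
    format: str = "BED",
    include_nuisance: bool = False,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write a Segmentation (or interval list) as BED or GFF3.

    BED is 0-based half-open with the cluster id as name and the
    per-segment score affinely scaled into [0, 1000]; GFF3 is 1-based
    inclusive with the raw score.
    """
    if isinstance(seg_or_intervals, Segmentation):
        ivs, raw = segmentation_to_intervals(seg_or_intervals, include_nuisance)
    else:
        ivs = list(seg_or_intervals)
        raw = list(scores) if scores is not None else [0.0] * len(ivs)
    fmt = format.upper()
    if fmt == "BED":
        if raw:
            lo, hi = min(raw), max(raw)
            span = hi - lo
            scaled = [1000.0 * (r - lo) / span if span > 0 else 0.0 for r in raw]
        else:
            scaled = []
        write_bed(ivs, path, scaled)
    elif fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for iv, r in zip(ivs, raw):
                attrs = f"ID={iv.name}" if iv.name else "."
                fh.write(
                    f"{iv.chromosome}\tsimseg\tsegment\t{iv.start}\t{iv.end}\t"
                    f"{r:g}\t{iv.strand}\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")


# ------------------------------------------------------- cluster model TSV

def save_cluster_model(model: ClusterModel, directory: str | Path, prefix: str = "model") -> None:
    """Serialize a ClusterModel to a TSV bundle for re-use across scans."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"label": model.labels}).to_csv(
        directory / f"{prefix}.labels.tsv", sep="\t", index=False
    )
    pd.DataFrame(model.centers).to_csv(
        directory / f"{prefix}.centers.tsv", sep="\t", index=False
    )
    if model.pos_cluster_sim is not None:
        pd.DataFrame(model.pos_cluster_sim).to_csv(
            directory / f"{prefix}.icor.tsv", sep="\t", index=False
        )
    if model.cluster_cluster_sim is not None:
        pd.DataFrame(model.cluster_cluster_sim).to_csv(
            directory / f"{prefix}.ccor.tsv", sep="\t", index=False
        )
    meta = {"K": model.K, "theta": model.theta, "seed": model.seed}
    with open(directory / f"{prefix}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_cluster_model(directory: str | Path, prefix: str = "model") -> ClusterModel:
    directory = Path(directory)
    labels = pd.read_csv(directory / f"{prefix}.labels.tsv", sep="\t")["label"].to_numpy()
    centers = pd.read_csv(directory / f"{prefix}.centers.tsv", sep="\t").to_numpy()
    with open(directory / f"{prefix}.meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    model = ClusterModel(
        labels=labels, centers=centers, K=int(meta["K"]),
        theta=float(meta["theta"]), seed=int(meta["seed"]),
    )
    icor = directory / f"{prefix}.icor.tsv"
    if icor.exists():
        model.pos_cluster_sim = pd.read_csv(icor, sep="\t").to_numpy()
    ccor = directory / f"{prefix}.ccor.tsv"
    if ccor.exists():
        model.cluster_cluster_sim = pd.read_csv(ccor, sep="\t").to_numpy()
    return model


# ------------------------------------------------------------------ config

_CONFIG_DEFAULTS = {
    # time-series processing
    "trafo": "raw",
    "dft.range": list(range(1, 8)),
    "dc.trafo": "ash",
    "use.snr": True,
    # clustering
    "K": 10,
    "nui.thresh": 0.6,
    # segmentation
    "scoring": "icor",
    "E": 1.0,
    "M": 100.0,
    "Mn": None,  # defaults to M
    "nui": 1.0,
    "nuisance.mode": "nu",
    "chunk-size": 0,  # 0 = no chunking
    "overlap": 0,
    # pre-segmentation
    "avg": 1000,
    "favg": 100,
    "minrd": 8,
    "minsg": 1000,
    "min.gap.len": 1000,
    # global
    "seed": 0,
    "cluster.scope": "preseg",  # or "global"
}


@dataclass
class RunConfig:
    """Validated pipeline parameters under their tool-vocabulary names."""

    params: dict = field(default_factory=dict)
    input_dir: Optional[str] = None
    output_dir: str = "simseg_out"
    targets: Optional[str] = None  # BED of annotation targets

    def __post_init__(self) -> None:
        merged = dict(_CONFIG_DEFAULTS)
        unknown = set(self.params) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged.update(self.params)
        self.params = merged
        self.validate()

    def __getitem__(self, key: str):
        return self.params[key]

    def validate(self) -> None:
        p = self.params
        if p["trafo"] not in ("raw", "ash") or p["dc.trafo"] not in ("raw", "ash"):
            raise ValueError("trafo / dc.trafo must be raw|ash")
        if p["K"] < 2:
            raise ValueError("K must be >= 2")
        if not (-1 <= p["nui.thresh"] <= 1):
            raise ValueError("nui.thresh must be in [-1, 1]")
        if p["scoring"] not in ("ccls", "icor", "ccor"):
            raise ValueError("scoring must be ccls|icor|ccor")
        if p["E"] < 1:
            raise ValueError("E must be >= 1")
        if p["M"] < 0 or (p["Mn"] is not None and p["Mn"] < 0):
            raise ValueError("M and Mn must be >= 0")
        if any(c < 1 for c in p["dft.range"]):
            raise ValueError("dft.range is 1-based")
        if p["favg"] > p["avg"]:
            raise ValueError("favg must be <= avg")
        if p["minrd"] <= 0:
            raise ValueError("minrd must be positive")
        if p["chunk-size"] and p["chunk-size"] <= 2 * p["overlap"]:
            raise ValueError("chunk-size must exceed 2 * overlap")
        if p["cluster.scope"] not in ("preseg", "global"):
            raise ValueError("cluster.scope must be preseg|global")


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        params=raw.get("params", {}),
        input_dir=raw.get("input_dir"),
        output_dir=raw.get("output_dir", "simseg_out"),
        targets=raw.get("targets"),
    )


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "params": config.params,
                "input_dir": config.input_dir,
                "output_dir": config.output_dir,
                "targets": config.targets,
            },
            fh,
        )
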
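"""Sliding-window scanning of genomic regions and window-to-call conversion."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import model as model_mod
from .encoding import ConservationTrack, encode_windows
from .intervals import GenomicInterval, cluster_by_overlap, make_windows

log = logging.getLogger(__name__)

__all__ = ["ScanResult", "generate_windows", "scan", "call_predictions",
           "write_window_scores", "read_window_scores"]


@dataclass
class ScanResult:
    windows: list[tuple[GenomicInterval, float]]
    calls: list[GenomicInterval] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def generate_windows(
    regions: Sequence[GenomicInterval],
    width: int = 100,
    step: int = 5,
    strands: str = "both",
) -> list[GenomicInterval]:
    """Windows over every region; ``strands="both"`` emits each window on
    both strands (identical coordinates, opposite orientation)."""
    if strands not in ("both", "+", "-", "region"):
        raise ValueError(f"invalid strands option {strands!r}")
    out: list[GenomicInterval] = []
    for region in regions:
        base = make_windows(region, width=width, step=step)
        if strands == "region":
            out.extend(base)
        elif strands == "both":
            for w in base:
                out.append(GenomicInterval(w.chrom, w.start, w.end, "+", w.name))
            for w in base:
                out.append(GenomicInterval(w.chrom, w.start, w.end, "-", w.name))
        else:
            for w in base:
                out.append(GenomicInterval(w.chrom, w.start, w.end, strands, w.name))
    return out


def scan(
    model: model_mod.Model,
    regions: Sequence[GenomicInterval],
    genome,
    track: ConservationTrack | None = None,
    fold_backend=None,
    width: int = 100,
    step: int = 5,
    strands: str = "both",
    batch_size: int = 512,
) -> ScanResult:
    """Score sliding windows over *regions* with a trained model.

    Windows come from :func:`rnaloci.intervals.make_windows` (shared code
    path) on each region and, by default, both strands.  A model with the
    conservation branch enabled requires a track.
    """
    if "C" in model.config.branches and track is None:
        raise ValueError(
            "model uses the conservation branch but no conservation track was given"
        )
    windows = generate_windows(regions, width=width, step=step, strands=strands)
    encoded = encode_windows(
        windows, genome, track, fold_backend,
        target_length=model.config.input_length, branches=model.config.branches,
    )
    scores = model_mod.predict(model, encoded, batch_size=batch_size)
    return ScanResult(
        windows=list(zip(windows, (float(s) for s in scores))),
        params={"width": width, "step": step, "strands": strands},
    )


def call_predictions(
    windows: Sequence[tuple[GenomicInterval, float]],
    threshold: float,
    merge: str = "cluster-max",
) -> list[GenomicInterval]:
    """Convert scored windows into locus calls.

    Windows scoring at least *threshold* are clustered by same-strand
    overlap; each cluster emits one call spanning its highest-scoring window
    (ties broken towards the leftmost window), with the cluster's maximum
    score.  ``merge="none"`` emits every above-threshold window as a call.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    if merge not in ("cluster-max", "none"):
        raise ValueError(f"unknown merge policy {merge!r}")
    above = [(iv, s) for iv, s in windows if s >= threshold]
    if merge == "none":
        return [iv.with_score(s) for iv, s in above]
    score_of = {}
    for iv, s in above:
        score_of[iv.key()] = max(s, score_of.get(iv.key(), -np.inf))
    calls = []
    for cluster in cluster_by_overlap([iv for iv, _ in above]):
        seen = set()
        members = []
        for iv in cluster:
            if iv.key() not in seen:
                seen.add(iv.key())
                members.append(iv)
        best = max(members, key=lambda iv: (score_of[iv.key()], -iv.start, -iv.end))
        calls.append(best.with_score(score_of[best.key()]))
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.strand))


def write_window_scores(
    windows: Sequence[tuple[GenomicInterval, float]], path: str | Path
) -> None:
    """bedGraph-like TSV: chrom, start, end, strand, score."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tscore\n")
        for iv, s in windows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{s:.6f}\n")


def read_window_scores(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, start, end, strand, score = line.rstrip("\n").split("\t")
            out.append(
                (GenomicInterval(chrom, int(start), int(end), strand), float(score))
            )
    return out
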
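"""Strand-aware genomic interval arithmetic and BED6 I/O.

All coordinates are 0-based, half-open (BED convention).  Intervals are the
shared currency of the whole package: annotated target loci, sliding scan
windows, and locus calls are all :class:`GenomicInterval` instances.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

__all__ = [
    "GenomicInterval",
    "BedParseError",
    "read_bed",
    "write_bed",
    "extend_and_merge",
    "make_windows",
    "is_hit",
    "cluster_by_overlap",
]


class BedParseError(ValueError):
    """A BED line that cannot be mapped onto a valid interval."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic span.

    Parameters
    ----------
    chrom : str
        Chromosome / contig identifier.
    start, end : int
        0-based half-open coordinates; ``0 <= start < end`` is enforced.
    strand : str
        ``"+"`` or ``"-"``.
    name : str
        Free-text label (BED column 4); defaults to ``"."``.
    score : float or None
        Optional score in arbitrary units; ``None`` round-trips as ``"."``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValueError(f"non-integer coordinates: {self.start!r}, {self.end!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with *other*; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def same_strand_overlap(self, other: "GenomicInterval") -> int:
        if self.strand != other.strand:
            return 0
        return self.overlap(other)

    def with_score(self, score: float | None) -> "GenomicInterval":
        return replace(self, score=score)

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


def _parse_strand(token: str, line_no: int) -> str:
    # tolerate the unicode minus occasionally produced by text extraction
    if token in ("-", "−"):
        return "-"
    if token == "+":
        return "+"
    raise BedParseError(f"line {line_no}: invalid strand field {token!r}")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals.

    Columns 4-6 map to name/score/strand when present.  A missing strand
    defaults to ``"+"`` (logged); a score of ``"."`` maps to ``None``.

    Raises
    ------
    BedParseError
        On non-integer coordinates, ``start >= end``, fewer than three
        columns, or an invalid strand symbol — naming the line number.
    """
    out: list[GenomicInterval] = []
    defaulted = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {line_no}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {line_no}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"line {line_no}: non-numeric score") from exc
            if len(fields) > 5 and fields[5] not in (".", ""):
                strand = _parse_strand(fields[5], line_no)
            else:
                strand = "+"
                defaulted += 1
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(f"line {line_no}: {exc}") from exc
    if defaulted:
        log.info("read_bed(%s): defaulted strand to '+' on %d line(s)", path, defaulted)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6.  Absent scores are written as ``"."``.

    ``read_bed(write_bed(X)) == X`` for scores representable with 10
    significant digits.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(float(iv.score), ".10g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def extend_and_merge(
    targets: Sequence[GenomicInterval],
    flank: int = 5000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Grow each interval by *flank* on both sides and merge per strand.

    Extension clips at 0 always, and at the chromosome end when
    *chrom_sizes* provides one.  Same-strand intervals that overlap or abut
    after extension collapse into one; opposite strands never merge.  The
    result is sorted by ``(chrom, start, end, strand)``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    extended = []
    for iv in targets:
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        if start != iv.start - flank or end != iv.end + flank:
            log.debug("extend_and_merge: clipped %s:%d-%d", iv.chrom, iv.start, iv.end)
        extended.append(replace(iv, start=start, end=end, score=None))
    merged: list[GenomicInterval] = []
    for iv in sorted(extended, key=lambda v: (v.chrom, v.strand, v.start, v.end)):
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.chrom == iv.chrom
            and last.strand == iv.strand
            and iv.start <= last.end  # overlap or abut
        ):
            merged[-1] = replace(last, end=max(last.end, iv.end))
        else:
            merged.append(iv)
    return sorted(merged, key=lambda v: (v.chrom, v.start, v.end, v.strand))


def make_windows(
    region: GenomicInterval, width: int = 100, step: int = 5
) -> list[GenomicInterval]:
    """Sliding windows over *region*: starts at ``region.start + k*step``
    while the window still fits.  Count is ``floor((len-width)/step)+1`` for
    ``len >= width``, else 0.  Windows inherit the region's strand."""
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    if region.length < width:
        log.debug(
            "make_windows: region %s:%d-%d shorter than width %d",
            region.chrom, region.start, region.end, width,
        )
        return []
    return [
        GenomicInterval(
            region.chrom, s, s + width, region.strand, f"{region.chrom}:{s}-{s + width}"
        )
        for s in range(region.start, region.end - width + 1, step)
    ]


def is_hit(
    prediction: GenomicInterval,
    target: GenomicInterval,
    min_frac: float = 0.5,
    denominator: str = "prediction",
) -> bool:
    """Fractional-overlap hit rule.

    True iff prediction and target share chromosome and strand and the
    overlap covers at least *min_frac* of the *denominator* interval
    (``"prediction"`` by default, ``"target"`` as the alternative); the
    boundary (exactly *min_frac*) counts as a hit.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    if denominator not in ("prediction", "target"):
        raise ValueError(f"unknown denominator {denominator!r}")
    ov = prediction.same_strand_overlap(target)
    if ov == 0:
        return False
    denom = prediction.length if denominator == "prediction" else target.length
    return ov / denom >= min_frac


def cluster_by_overlap(
    intervals: Sequence[GenomicInterval],
) -> list[list[GenomicInterval]]:
    """Single-linkage clustering of intervals by strict same-strand overlap
    (>0 bp; abutting intervals do NOT join).  Clusters are ordered by
    (chrom, strand, start); members keep coordinate order."""
    clusters: list[list[GenomicInterval]] = []
    cur: list[GenomicInterval] = []
    cur_end = -1
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.strand, v.start, v.end)):
        if cur and iv.chrom == cur[0].chrom and iv.strand == cur[0].strand and iv.start < cur_end:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [iv]
            cur_end = iv.end
    if cur:
        clusters.append(cur)
    return clusters
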
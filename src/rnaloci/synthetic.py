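"""Synthetic benchmark generator: genome, conservation track, planted loci.

Positives are planted hairpins (random arm + loop + reverse-complemented
arm) with elevated per-base conservation.  Two decoy classes each carry only
one of the two signals, so they are exactly the "hard cases" consensus
mining should discover:

* ``sequence_only``  — a hairpin with background-level conservation
* ``conserved_only`` — elevated conservation over plain background sequence

Everything is deterministic per seed and written as plain-text formats
(FASTA, fixedStep wiggle, BED6).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .encoding import ConservationTrack, reverse_complement
from .intervals import GenomicInterval, extend_and_merge
from .background import TrainingRun

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "BenchmarkSuite",
    "plant_hairpin",
    "simulate_genome",
    "benchmark_suite",
]

DECOY_CLASSES = ("sequence_only", "conserved_only")


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of one synthetic benchmark; defaults run end-to-end in a
    few minutes on one CPU.

    Positives are heterogeneous, like real locus classes: each draws its own
    conservation elevation from ``[cons_mean_pos_min, cons_mean_pos]`` and
    carries up to ``stem_mutation_max`` random arm mismatches, while decoys
    are clean single-signal loci (a perfect unconserved hairpin, or a fully
    conserved non-hairpin).  A model must therefore combine branches to rank
    weak positives above strong decoys — the separation hard-negative mining
    is designed to teach.
    """

    n_chroms: int = 3
    chrom_length: int = 50_000
    n_positives: int = 60
    stem_len: int = 30
    loop_len: int = 15
    cons_mean_pos: float = 2.0
    cons_mean_pos_min: float = 0.5
    cons_mean_bg: float = 0.0
    cons_sd: float = 0.75
    stem_mutation_max: int = 6
    decoy_classes: tuple[str, ...] = DECOY_CLASSES
    n_decoys_per_class: int = 20
    gc_background: float = 0.42
    min_spacing: int = 100
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "decoy_classes", tuple(self.decoy_classes))
        if self.stem_len < 4:
            raise SpecError("stem_len must be >= 4")
        if self.loop_len < 3:
            raise SpecError("loop_len must be >= 3")
        if self.cons_mean_pos_min > self.cons_mean_pos:
            raise SpecError("cons_mean_pos_min must be <= cons_mean_pos")
        if not (0 <= self.stem_mutation_max <= self.stem_len // 2):
            raise SpecError("stem_mutation_max must be in [0, stem_len // 2]")
        if 2 * self.stem_len + self.loop_len > 100:
            raise SpecError("locus length 2*stem_len + loop_len must be <= 100")
        if not (0 < self.gc_background < 1):
            raise SpecError("gc_background must be in (0, 1)")
        for c in self.decoy_classes:
            if c not in DECOY_CLASSES:
                raise SpecError(f"unknown decoy class {c!r}")
        if self.n_chroms < 1 or self.chrom_length < 1000:
            raise SpecError("need n_chroms >= 1 and chrom_length >= 1000")

    @property
    def locus_length(self) -> int:
        return 2 * self.stem_len + self.loop_len

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGenomeSpec":
        d = json.loads(text)
        if "decoy_classes" in d:
            d["decoy_classes"] = tuple(d["decoy_classes"])
        return cls(**d)


def plant_hairpin(stem_len: int, loop_len: int, rng: np.random.Generator) -> str:
    """Random arm + random loop + reverse complement of the arm; folds into
    a clean stem-loop with at least *stem_len* base pairs."""
    if stem_len < 4:
        raise SpecError("stem_len must be >= 4")
    if loop_len < 3:
        raise SpecError("loop_len must be >= 3")
    bases = np.array(list("ACGT"))
    arm = "".join(rng.choice(bases, size=stem_len))
    loop = "".join(rng.choice(bases, size=loop_len))
    return arm + loop + reverse_complement(arm)


def _mutate_arm(hairpin: str, spec: SyntheticGenomeSpec,
                rng: np.random.Generator) -> str:
    """Introduce 0..stem_mutation_max mismatches into the 3' arm."""
    n_mut = int(rng.integers(0, spec.stem_mutation_max + 1))
    if n_mut == 0:
        return hairpin
    arm_start = spec.stem_len + spec.loop_len
    chars = list(hairpin)
    sites = rng.choice(spec.stem_len, size=n_mut, replace=False)
    for off in sites:
        i = arm_start + int(off)
        chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


def _random_background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _place_loci(
    n_loci: int, locus_len: int, chrom_len: int, spacing: int, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping starts with >= *spacing* bp between loci and to the
    chromosome ends, uniformly via the gap-allocation trick."""
    slack = chrom_len - n_loci * locus_len - (n_loci + 1) * spacing
    if slack < 0:
        raise SpecError(
            f"{n_loci} loci of {locus_len} bp with {spacing} bp spacing do not "
            f"fit in a {chrom_len} bp chromosome"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n_loci))
    starts = []
    for i, c in enumerate(cuts):
        starts.append(int(c + spacing + i * (locus_len + spacing)))
    return starts


@dataclass
class SyntheticGenome:
    spec: SyntheticGenomeSpec
    sequences: dict[str, str]
    track: ConservationTrack
    positives: list[GenomicInterval]
    decoys: list[GenomicInterval]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa, conservation.wig, positives.bed, decoys.bed and
        the resolved spec; returns the paths."""
        from .intervals import write_bed

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "wiggle": outdir / "conservation.wig",
            "positives": outdir / "positives.bed",
            "decoys": outdir / "decoys.bed",
            "spec": outdir / "spec.resolved.json",
        }
        with open(paths["fasta"], "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        self.track.to_wiggle(paths["wiggle"])
        write_bed(self.positives, paths["positives"])
        write_bed(self.decoys, paths["decoys"])
        self.spec.to_json(paths["spec"])
        return paths


def simulate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate the full synthetic benchmark in memory.

    Background bases are i.i.d. with the configured GC; hairpins are
    implanted at recorded positions on random strands; conservation is drawn
    per-base from a normal with elevated mean inside positives and
    ``conserved_only`` decoys.
    """
    rng = np.random.default_rng(spec.seed)
    n_decoys = spec.n_decoys_per_class * len(spec.decoy_classes)
    total_loci = spec.n_positives + n_decoys
    per_chrom = int(np.ceil(total_loci / spec.n_chroms))
    # feasibility check before any output
    _place_loci(per_chrom, spec.locus_length, spec.chrom_length, spec.min_spacing,
                np.random.default_rng(0))

    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    # deal loci round-robin so every chromosome carries all classes
    locus_kinds: list[str] = ["positive"] * spec.n_positives
    for cls in spec.decoy_classes:
        locus_kinds += [cls] * spec.n_decoys_per_class
    order = rng.permutation(len(locus_kinds))
    assignment: dict[str, list[str]] = {c: [] for c in chroms}
    for pos, idx in enumerate(order):
        assignment[chroms[pos % spec.n_chroms]].append(locus_kinds[idx])

    sequences: dict[str, str] = {}
    cons: dict[str, np.ndarray] = {}
    positives: list[GenomicInterval] = []
    decoys: list[GenomicInterval] = []
    for chrom in chroms:
        kinds = assignment[chrom]
        seq = _random_background(spec.chrom_length, spec.gc_background, rng)
        scores = rng.normal(spec.cons_mean_bg, spec.cons_sd, size=spec.chrom_length)
        starts = _place_loci(
            len(kinds), spec.locus_length, spec.chrom_length, spec.min_spacing, rng
        )
        for kind, start in zip(kinds, starts):
            end = start + spec.locus_length
            strand = "+" if rng.integers(2) == 0 else "-"
            if kind in ("positive", "sequence_only"):
                hp = plant_hairpin(spec.stem_len, spec.loop_len, rng)
                if kind == "positive" and spec.stem_mutation_max > 0:
                    hp = _mutate_arm(hp, spec, rng)
                oriented = hp if strand == "+" else reverse_complement(hp)
                seq[start:end] = list(oriented)
            if kind in ("positive", "conserved_only"):
                # decoys always get the full elevation; positives vary
                mean = spec.cons_mean_pos if kind == "conserved_only" else float(
                    rng.uniform(spec.cons_mean_pos_min, spec.cons_mean_pos)
                )
                scores[start:end] = rng.normal(
                    mean, spec.cons_sd, size=spec.locus_length
                )
            if kind == "positive":
                positives.append(GenomicInterval(
                    chrom, start, end, strand, f"pos_{len(positives)}"
                ))
            else:
                decoys.append(GenomicInterval(
                    chrom, start, end, strand, f"decoy_{kind}_{len(decoys)}"
                ))
        sequences[chrom] = "".join(seq)
        cons[chrom] = scores
    track = ConservationTrack()
    for chrom, arr in cons.items():
        track.set_dense(chrom, arr)
    genome = SyntheticGenome(spec, sequences, track, positives, decoys)
    log.info(
        "simulated %d chroms x %d bp: %d positives, %d decoys",
        spec.n_chroms, spec.chrom_length, len(positives), len(decoys),
    )
    return genome


@dataclass
class BenchmarkSuite:
    """Chromosome-holdout split of a synthetic genome.

    The last chromosome is fully left out for final scanning evaluation; the
    second-to-last provides the test split for ensemble model selection; the
    rest train.  Training positives are resized to the model input length
    (centered on the locus) so training examples and scan windows share the
    same geometry.
    """

    genome: SyntheticGenome
    run: TrainingRun
    candidate_regions: list[GenomicInterval]
    scan_regions: list[GenomicInterval]
    left_out_chrom: str
    left_out_targets: list[GenomicInterval]
    left_out_scan_regions: list[GenomicInterval]


def _resize_centered(
    iv: GenomicInterval, length: int, chrom_len: int
) -> GenomicInterval:
    center = (iv.start + iv.end) // 2
    start = max(0, min(center - length // 2, chrom_len - length))
    return replace(iv, start=start, end=start + length)


def benchmark_suite(
    genome: SyntheticGenome, input_length: int = 100, flank: int = 5000
) -> BenchmarkSuite:
    """Carve a chromosome-holdout benchmark out of a synthetic genome."""
    spec = genome.spec
    if spec.n_chroms < 3:
        raise SpecError("need at least 3 chromosomes for a holdout benchmark")
    chroms = sorted(genome.sequences)
    left_out = chroms[-1]
    test_chrom = chroms[-2]
    split = {c: "train" for c in chroms[:-2]}
    split[test_chrom] = "test"

    sizes = genome.chrom_sizes
    inner = [p for p in genome.positives if p.chrom != left_out]
    train_positives = [
        _resize_centered(p, input_length, sizes[p.chrom]) for p in inner
    ]
    run = TrainingRun(positives=train_positives, negatives=[], split=split,
                      seed=spec.seed)

    # candidate background: everything >= min_spacing away from any locus
    loci_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in list(genome.positives) + list(genome.decoys):
        loci_by_chrom.setdefault(iv.chrom, []).append(iv)
    candidates = []
    for chrom in chroms[:-1]:
        blocked = sorted(
            (max(0, iv.start - spec.min_spacing), iv.end + spec.min_spacing)
            for iv in loci_by_chrom.get(chrom, [])
        )
        cursor = 0
        pieces = []
        for b0, b1 in blocked:
            if b0 - cursor >= input_length:
                pieces.append((cursor, b0))
            cursor = max(cursor, b1)
        if sizes[chrom] - cursor >= input_length:
            pieces.append((cursor, sizes[chrom]))
        for j, (a, b) in enumerate(pieces):
            candidates.append(GenomicInterval(chrom, a, b, "+", f"bg_{chrom}_{j}"))

    # scan regions are strandless spans (scanning covers both strands), so
    # collapse target strands before merging to avoid duplicated windows
    unstranded = lambda ivs: [replace(iv, strand="+") for iv in ivs]
    scan_regions = extend_and_merge(unstranded(inner), flank=flank, chrom_sizes=sizes)
    left_targets = [p for p in genome.positives if p.chrom == left_out]
    left_scan = extend_and_merge(
        unstranded(left_targets), flank=flank, chrom_sizes=sizes
    )
    return BenchmarkSuite(
        genome=genome,
        run=run,
        candidate_regions=candidates,
        scan_regions=scan_regions,
        left_out_chrom=left_out,
        left_out_targets=left_targets,
        left_out_scan_regions=left_scan,
    )
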
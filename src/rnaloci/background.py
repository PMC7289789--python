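"""Iterative background selection: random negatives, model ensemble,
consensus false-positive ("hard case") mining, and enhanced-set retraining.

The scheme has two steps.  First an ensemble of models is trained, each on
the same positives but an independently re-sampled random negative set at a
fixed negative:positive ratio.  Every model then scans large background
regions; windows that many models mis-score as positive are extracted as
hard negatives.  Finally the best ensemble member's training set, enhanced
with the hard negatives, is used to train the final model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import model as model_mod
from .encoding import ConservationTrack, EncodedWindow, encode_windows
from .intervals import GenomicInterval, cluster_by_overlap, is_hit
from .model import Model, ModelConfig
from .scanner import generate_windows

log = logging.getLogger(__name__)

__all__ = [
    "TrainingRun",
    "HardNegativeSet",
    "EnsembleMember",
    "InsufficientBackgroundError",
    "sample_random_negatives",
    "train_ensemble",
    "collect_hard_negatives",
    "select_best_model",
    "iterate_train",
]


class InsufficientBackgroundError(RuntimeError):
    pass


@dataclass
class TrainingRun:
    """Positives, negatives and a by-chromosome split assignment."""

    positives: list[GenomicInterval]
    negatives: list[GenomicInterval]
    split: dict[str, str]  # chrom -> "train" | "validation" | "test"
    seed: int

    def role(self, iv: GenomicInterval) -> str:
        return self.split.get(iv.chrom, "train")

    def validate(self, ratio: int | None = None, min_frac: float = 0.5) -> None:
        for neg in self.negatives:
            for pos in self.positives:
                if is_hit(neg, pos, min_frac=min_frac):
                    raise AssertionError(
                        f"negative {neg.chrom}:{neg.start}-{neg.end}{neg.strand} "
                        "overlaps a positive on the same strand"
                    )
        if ratio is not None:
            if abs(len(self.negatives) - ratio * len(self.positives)) > ratio:
                raise AssertionError("negative:positive ratio violated")


@dataclass
class HardNegativeSet:
    intervals: list[GenomicInterval]
    support: dict[tuple, int]  # interval.key() -> number of flagging models
    n_models: int

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class EnsembleMember:
    index: int
    seed: int
    model: Model
    negatives: list[GenomicInterval]
    metrics: dict[str, float] = field(default_factory=dict)


def sample_random_negatives(
    positives: Sequence[GenomicInterval],
    candidate_regions: Sequence[GenomicInterval],
    ratio: int = 4,
    seed: int = 0,
    max_tries_per_draw: int = 200,
) -> list[GenomicInterval]:
    """Length-matched random negatives at *ratio* per positive.

    Each negative copies the length of its positive, lands uniformly (by
    available bp) inside the candidate regions on a random strand, and is
    rejected on same-strand overlap with any positive or previously drawn
    negative.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    fitting_any = [r for r in candidate_regions if any(
        r.length >= p.length for p in positives)]
    if positives and not fitting_any:
        raise InsufficientBackgroundError(
            "no candidate region can host even one positive-length negative"
        )
    drawn: list[GenomicInterval] = []
    shortfall = 0
    for p_idx, pos in enumerate(positives):
        n = pos.length
        regions = [r for r in candidate_regions if r.length >= n]
        if not regions:
            raise InsufficientBackgroundError(
                f"no candidate region fits a negative of length {n}"
            )
        weights = np.array([r.length - n + 1 for r in regions], dtype=float)
        weights /= weights.sum()
        for k in range(ratio):
            placed = False
            for _ in range(max_tries_per_draw):
                region = regions[rng.choice(len(regions), p=weights)]
                start = int(rng.integers(region.start, region.end - n + 1))
                strand = "+" if rng.integers(2) == 0 else "-"
                cand = GenomicInterval(
                    region.chrom, start, start + n, strand,
                    f"neg_{p_idx}_{k}",
                )
                if any(cand.same_strand_overlap(p) > 0 for p in positives):
                    continue
                if any(cand.same_strand_overlap(d) > 0 for d in drawn):
                    continue
                drawn.append(cand)
                placed = True
                break
            if not placed:
                shortfall += 1
    if shortfall:
        raise InsufficientBackgroundError(
            f"could not place {shortfall} negative(s) after rejection sampling"
        )
    return drawn


def _split_examples(
    encoded: Sequence[EncodedWindow], split: Mapping[str, str]
) -> dict[str, list[EncodedWindow]]:
    out: dict[str, list[EncodedWindow]] = {"train": [], "validation": [], "test": []}
    for w in encoded:
        out[split.get(w.interval.chrom, "train")].append(w)
    return out


def _test_metrics(model: Model, test: Sequence[EncodedWindow], threshold: float = 0.5):
    from .evaluation import confusion_prelabelled, prf

    scores = model_mod.predict(model, test)
    labels = [w.label for w in test]
    tp, fp, fn, tn = confusion_prelabelled(scores, labels, threshold)
    p, s, f1 = prf(tp, fp, fn)
    return {"precision": p, "sensitivity": s, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def train_ensemble(
    positives: Sequence[GenomicInterval],
    candidate_regions: Sequence[GenomicInterval],
    genome,
    track: ConservationTrack | None,
    fold_backend=None,
    *,
    config: ModelConfig,
    n_models: int = 50,
    ratio: int = 4,
    seed: int = 0,
    split: Mapping[str, str] | None = None,
    encoded_positives: Sequence[EncodedWindow] | None = None,
) -> list[EnsembleMember]:
    """Train *n_models* classifiers, each with an independently re-sampled
    negative set (seeds ``seed + i``), and record per-model test metrics."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    split = dict(split or {})
    if encoded_positives is None:
        encoded_positives = encode_windows(
            positives, genome, track, fold_backend,
            target_length=config.input_length, branches=config.branches, label=1,
        )
    pos_split = _split_examples(encoded_positives, split)
    members = []
    for i in range(n_models):
        member_seed = seed + i
        negatives = sample_random_negatives(
            positives, candidate_regions, ratio=ratio, seed=member_seed
        )
        encoded_neg = encode_windows(
            negatives, genome, track, fold_backend,
            target_length=config.input_length, branches=config.branches, label=0,
        )
        neg_split = _split_examples(encoded_neg, split)
        train_set = pos_split["train"] + neg_split["train"]
        val_set = pos_split["validation"] + neg_split["validation"]
        test_set = pos_split["test"] + neg_split["test"]
        cfg = replace(config, seed=member_seed)
        m = model_mod.build_model(cfg)
        model_mod.train(m, train_set, val_examples=val_set or None, config=cfg)
        member = EnsembleMember(index=i, seed=member_seed, model=m, negatives=negatives)
        if test_set:
            member.metrics = _test_metrics(m, test_set)
        members.append(member)
        log.info("ensemble member %d/%d: %s", i + 1, n_models, member.metrics)
    return members


def collect_hard_negatives(
    members: Sequence[EnsembleMember] | Sequence[Model],
    scan_regions: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    genome,
    track: ConservationTrack | None = None,
    fold_backend=None,
    *,
    score_threshold: float = 0.5,
    support_threshold: int = 25,
    width: int = 100,
    step: int = 5,
    strands: str = "both",
    min_frac: float = 0.5,
    precomputed: tuple[list[GenomicInterval], np.ndarray] | None = None,
) -> HardNegativeSet:
    """Consensus false positives across the ensemble.

    Every model scores the same scan windows (encoded once).  A window is a
    false positive for a model when its score reaches *score_threshold* and
    it hits no target under the overlap rule.  False-positive windows are
    clustered by same-strand overlap; a cluster's support is the number of
    distinct models contributing at least one window, and clusters with
    support >= *support_threshold* emit their highest-scoring window (ties
    towards the leftmost) as one representative hard negative.

    *precomputed* optionally supplies (windows, score_matrix) with scores of
    shape (n_models, n_windows) to avoid re-scanning.
    """
    models = [m.model if isinstance(m, EnsembleMember) else m for m in members]
    if support_threshold > len(models):
        raise ValueError("support_threshold exceeds the number of models")
    if precomputed is not None:
        windows, scores = precomputed
        scores = np.asarray(scores)
    else:
        windows = generate_windows(scan_regions, width=width, step=step, strands=strands)
        encoded = encode_windows(
            windows, genome, track, fold_backend,
            target_length=models[0].config.input_length,
            branches=models[0].config.branches,
        )
        scores = np.stack([model_mod.predict(m, encoded) for m in models])

    hits_target = np.array(
        [any(is_hit(w, t, min_frac=min_frac) for t in targets) for w in windows]
    )
    fp_mask = (scores >= score_threshold) & ~hits_target[None, :]  # (M, W)
    flagged_idx = np.flatnonzero(fp_mask.any(axis=0))
    if flagged_idx.size == 0:
        return HardNegativeSet([], {}, len(models))

    by_key = {windows[i].key(): i for i in flagged_idx}
    clusters = cluster_by_overlap([windows[i] for i in flagged_idx])
    chosen: list[GenomicInterval] = []
    support_map: dict[tuple, int] = {}
    for cluster in clusters:
        idxs = sorted({by_key[iv.key()] for iv in cluster})
        support = int(np.sum(fp_mask[:, idxs].any(axis=1)))
        if support < support_threshold:
            continue
        # representative: highest score among flagged (window, model) pairs
        best_i, best_score = None, -np.inf
        for i in idxs:
            s = float(scores[fp_mask[:, i], i].max())
            w = windows[i]
            if s > best_score or (
                s == best_score and (w.start, w.end) < (windows[best_i].start, windows[best_i].end)
            ):
                best_i, best_score = i, s
        rep = windows[best_i].with_score(support / len(models))
        rep = replace(rep, name=f"hard_neg_{len(chosen)}")
        chosen.append(rep)
        support_map[rep.key()] = support
    return HardNegativeSet(chosen, support_map, len(models))


def select_best_model(
    members: Sequence[EnsembleMember], metric: str = "f1"
) -> EnsembleMember:
    """Arg-max member by test-set metric; ties break to the lower index."""
    if not members:
        raise ValueError("no ensemble members")
    if any(metric not in m.metrics for m in members):
        raise ValueError(f"metric {metric!r} missing from some members")
    return max(members, key=lambda m: (m.metrics[metric], -m.index))


def iterate_train(
    positives: Sequence[GenomicInterval],
    candidate_regions: Sequence[GenomicInterval],
    scan_regions: Sequence[GenomicInterval],
    genome,
    track: ConservationTrack | None = None,
    fold_backend=None,
    *,
    config: ModelConfig,
    targets: Sequence[GenomicInterval] | None = None,
    n_models: int = 50,
    ratio: int = 4,
    support_threshold: int = 25,
    score_threshold: float = 0.5,
    width: int = 100,
    step: int = 5,
    strands: str = "both",
    seed: int = 0,
    split: Mapping[str, str] | None = None,
    retrain: str = "scratch",
) -> tuple[Model, HardNegativeSet, dict]:
    """Full two-step pipeline; returns (final model, hard negatives,
    provenance record).

    The final model is retrained (from scratch by default, or fine-tuned
    with ``retrain="finetune"``) with the best ensemble member's seed on its
    positives + random negatives + mined hard negatives; hard negatives on
    held-out-split chromosomes are kept out of the training portion.
    """
    if retrain not in ("scratch", "finetune"):
        raise ValueError(f"unknown retrain mode {retrain!r}")
    split = dict(split or {})
    targets = list(targets if targets is not None else positives)

    encoded_positives = encode_windows(
        positives, genome, track, fold_backend,
        target_length=config.input_length, branches=config.branches, label=1,
    )
    members = train_ensemble(
        positives, candidate_regions, genome, track, fold_backend,
        config=config, n_models=n_models, ratio=ratio, seed=seed, split=split,
        encoded_positives=encoded_positives,
    )
    hard = collect_hard_negatives(
        members, scan_regions, targets, genome, track, fold_backend,
        score_threshold=score_threshold, support_threshold=support_threshold,
        width=width, step=step, strands=strands,
    )
    best = select_best_model(members)
    if len(hard) == 0:
        log.warning("no consensus hard negatives found; retraining on the "
                    "best member's unchanged set")

    enhanced_negatives = list(best.negatives) + list(hard.intervals)
    encoded_neg = encode_windows(
        best.negatives, genome, track, fold_backend,
        target_length=config.input_length, branches=config.branches, label=0,
    )
    encoded_hard = encode_windows(
        hard.intervals, genome, track, fold_backend,
        target_length=config.input_length, branches=config.branches, label=0,
    )
    pos_split = _split_examples(encoded_positives, split)
    neg_split = _split_examples(encoded_neg + encoded_hard, split)
    train_set = pos_split["train"] + neg_split["train"]
    val_set = pos_split["validation"] + neg_split["validation"]

    cfg = replace(config, seed=best.seed)
    if retrain == "scratch":
        final = model_mod.build_model(cfg)
    else:
        final = best.model
    model_mod.train(final, train_set, val_examples=val_set or None, config=cfg)

    provenance = {
        "seed": seed,
        "n_models": n_models,
        "ratio": ratio,
        "support_threshold": support_threshold,
        "score_threshold": score_threshold,
        "scan": {"width": width, "step": step, "strands": strands},
        "members": [
            {"index": m.index, "seed": m.seed, **m.metrics} for m in members
        ],
        "best_index": best.index,
        "retrain": retrain,
        "hard_negatives": {
            "count": len(hard),
            "supports": sorted(hard.support.values(), reverse=True),
        },
        "enhanced_set": {
            "n_positives": len(positives),
            "n_random_negatives": len(best.negatives),
            "n_hard_negatives": len(hard),
            "n_negatives_total": len(enhanced_negatives),
            "n_train_examples": len(train_set),
        },
    }
    return final, hard, provenance
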
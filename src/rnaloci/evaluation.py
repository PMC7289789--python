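"""Benchmark metrics: the two evaluation modes, PR curves and baselines.

Two modes mirror how locus predictors are benchmarked in practice:

* ``pre_labelled`` — a fixed candidate set with known labels, thresholded
  into a standard confusion table.
* ``scanning``     — calls from a sliding-window scan matched to annotated
  target loci by the fractional-overlap hit rule; sensitivity counts
  targets found, precision counts calls that hit.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, is_hit

__all__ = [
    "EvaluationReport",
    "UnattainableSensitivityError",
    "confusion_scanning",
    "confusion_prelabelled",
    "prf",
    "pr_curve_prelabelled",
    "pr_curve_scanning",
    "threshold_at_sensitivity",
    "fp_spacing",
    "expression_baseline",
]


class UnattainableSensitivityError(ValueError):
    """Requested sensitivity exceeds the curve's maximum."""


@dataclass
class EvaluationReport:
    mode: str  # "pre_labelled" | "scanning"
    threshold: float
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    f1: float
    tn: int | None = None
    scanned_bp: int | None = None
    counting: str = "cluster-max"  # window->call policy used, scanning mode

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path) -> None:
        d = asdict(self)
        keys = list(d)
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            fh.write("\t".join("" if d[k] is None else str(d[k]) for k in keys) + "\n")


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, sensitivity, F1 with total conventions: a zero denominator
    yields 0, and F1 is computed from the unrounded P and S."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    s = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * s / (p + s) if p + s else 0.0
    return p, s, f1


def confusion_scanning(
    calls: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    min_frac: float = 0.5,
    denominator: str = "prediction",
) -> tuple[int, int, int]:
    """Target-level TP/FN, call-level FP.

    TP = targets hit by at least one call; FP = calls hitting no target
    (duplicate hits on one target are neither extra TPs nor FPs);
    FN = targets - TP.
    """
    tp = 0
    hit_targets = set()
    fp = 0
    for call in calls:
        hits = [
            i
            for i, t in enumerate(targets)
            if is_hit(call, t, min_frac=min_frac, denominator=denominator)
        ]
        if hits:
            hit_targets.update(hits)
        else:
            fp += 1
    tp = len(hit_targets)
    return tp, fp, len(targets) - tp


def confusion_prelabelled(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[int, int, int, int]:
    """Standard thresholded confusion counts (TP, FP, FN, TN); a score equal
    to the threshold predicts positive."""
    if len(scores) != len(labels):
        raise ValueError(f"{len(scores)} scores but {len(labels)} labels")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fp, fn, tn


def pr_curve_prelabelled(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] | None = None,
) -> list[tuple[float, float, float]]:
    """(threshold, precision, sensitivity) points; the default grid is the
    sorted set of observed scores (the exact curve)."""
    if thresholds is None:
        thresholds = sorted(set(float(s) for s in scores))
    points = []
    for t in thresholds:
        tp, fp, fn, _ = confusion_prelabelled(scores, labels, t)
        p, s, _ = prf(tp, fp, fn)
        points.append((float(t), p, s))
    _assert_sensitivity_monotone(points)
    return points


def pr_curve_scanning(
    windows: Sequence[tuple[GenomicInterval, float]],
    targets: Sequence[GenomicInterval],
    thresholds: Sequence[float] | None = None,
    min_frac: float = 0.5,
    merge: str = "cluster-max",
    max_points: int = 160,
) -> list[tuple[float, float, float]]:
    """Scanning-mode PR curve: at each threshold, windows are converted to
    calls (scanner policy *merge*) and scored against *targets*.  The default
    grid is the observed window scores, quantile-thinned to *max_points*."""
    from .scanner import call_predictions  # local import avoids a cycle

    if thresholds is None:
        uniq = np.unique([s for _, s in windows])
        if uniq.size > max_points:
            uniq = np.quantile(uniq, np.linspace(0, 1, max_points))
        thresholds = [float(t) for t in uniq]
    points = []
    for t in sorted(thresholds):
        calls = call_predictions(windows, t, merge=merge)
        tp, fp, fn = confusion_scanning(calls, targets, min_frac=min_frac)
        p, s, _ = prf(tp, fp, fn)
        points.append((float(t), p, s))
    if merge == "none":
        # under cluster-max merging a rising threshold can split a cluster so
        # that its new representative hits a target the old one missed, so
        # strict monotonicity only holds for unmerged window-level calls
        _assert_sensitivity_monotone(points)
    return points


def _assert_sensitivity_monotone(points: list[tuple[float, float, float]]) -> None:
    for (t0, _, s0), (t1, _, s1) in zip(points, points[1:]):
        if t1 >= t0 and s1 > s0 + 1e-12:
            raise AssertionError("sensitivity increased with threshold")


def threshold_at_sensitivity(
    curve: Sequence[tuple[float, float, float]], target_s: float
) -> float:
    """Highest threshold whose sensitivity still reaches *target_s*."""
    if not (0 < target_s <= 1):
        raise ValueError("target sensitivity must be in (0, 1]")
    ok = [t for t, _, s in curve if s >= target_s]
    if not ok:
        best = max((s for _, _, s in curve), default=0.0)
        raise UnattainableSensitivityError(
            f"maximum sensitivity {best:.3f} < requested {target_s:.3f}"
        )
    return max(ok)


def fp_spacing(fp: int, scanned_bp: int) -> float:
    """Scanned bases per false positive; ``inf`` when there are none."""
    if fp < 0 or scanned_bp <= 0:
        raise ValueError("need fp >= 0 and scanned_bp > 0")
    return math.inf if fp == 0 else scanned_bp / fp


def expression_baseline(
    peaks: Sequence[tuple[GenomicInterval, float]],
    targets: Sequence[GenomicInterval],
    percentiles: Sequence[float],
    min_frac: float = 0.5,
) -> list[tuple[float, float, float]]:
    """Naive expression-ranked baseline.

    For each percentile, the top fraction of peaks by decreasing expression
    (ties broken by genomic order) are treated as predicted positives, and
    (percentile, precision, sensitivity) is computed under the hit rule.
    """
    for q in percentiles:
        if not (0 < q <= 100):
            raise ValueError("percentiles must be in (0, 100]")
    ranked = sorted(
        peaks, key=lambda pe: (-pe[1], pe[0].chrom, pe[0].start, pe[0].end, pe[0].strand)
    )
    points = []
    for q in percentiles:
        k = max(1, int(round(len(ranked) * q / 100.0))) if ranked else 0
        calls = [iv for iv, _ in ranked[:k]]
        tp, fp, fn = confusion_scanning(calls, targets, min_frac=min_frac)
        p, s, _ = prf(tp, fp, fn)
        points.append((float(q), p, s))
    return points


def write_pr_curve(points: Sequence[tuple[float, float, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tprecision\tsensitivity\n")
        for t, p, s in points:
            fh.write(f"{t:.6f}\t{p:.6f}\t{s:.6f}\n")


def report_scanning(
    windows: Sequence[tuple[GenomicInterval, float]],
    targets: Sequence[GenomicInterval],
    threshold: float,
    scanned_bp: int | None = None,
    min_frac: float = 0.5,
    merge: str = "cluster-max",
) -> EvaluationReport:
    from .scanner import call_predictions

    calls = call_predictions(windows, threshold, merge=merge)
    tp, fp, fn = confusion_scanning(calls, targets, min_frac=min_frac)
    p, s, f1 = prf(tp, fp, fn)
    return EvaluationReport(
        mode="scanning", threshold=float(threshold), tp=tp, fp=fp, fn=fn,
        precision=p, sensitivity=s, f1=f1, scanned_bp=scanned_bp, counting=merge,
    )


def report_prelabelled(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> EvaluationReport:
    tp, fp, fn, tn = confusion_prelabelled(scores, labels, threshold)
    p, s, f1 = prf(tp, fp, fn)
    return EvaluationReport(
        mode="pre_labelled", threshold=float(threshold), tp=tp, fp=fp, fn=fn,
        precision=p, sensitivity=s, f1=f1, tn=tn, counting="n/a",
    )
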
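"""Object-level and image-level evaluation of egg detections.

Object level: predictions are matched one-to-one to ground-truth boxes
greedily in descending IoU order (a pair qualifies only when IoU is strictly
above the threshold); matched pairs are true positives, unmatched predictions
false positives, unmatched truths missed detections.  Precision, recall and
F1 follow from the match.

Image level: for each image with true count TC and automatic count AC,

* counting error  = (TC - AC) / TC          (signed relative error)
* counting accuracy = 1 - |TC - AC| / TC
* miss rate       = missed detections / TC

and r-squared compares predicted against true counts across images.  The
confidence-threshold sweep re-applies the confidence filter over a grid
(default 0.3 to 0.7 in steps of 0.05) and reports the threshold maximizing
mean F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .detection import filter_confidence
from .geometry import Box, pairwise_iou

__all__ = [
    "MatchResult",
    "ObjectMetrics",
    "ImageMetrics",
    "SweepRow",
    "match_boxes",
    "object_metrics",
    "image_metrics",
    "r_squared",
    "threshold_sweep",
]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one truth/prediction pairing for a single image."""

    pairs: tuple[tuple[int, int, float], ...]  # (truth idx, pred idx, IoU)
    n_truth: int
    n_pred: int

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return self.n_pred - self.tp

    @property
    def missed(self) -> int:
        return self.n_truth - self.tp


@dataclass(frozen=True)
class ObjectMetrics:
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class ImageMetrics:
    counting_error: float | None  # signed: (TC - AC) / TC
    counting_accuracy: float | None  # 1 - |TC - AC| / TC
    miss_rate: float | None
    true_count: int
    automatic_count: int


@dataclass(frozen=True)
class SweepRow:
    tau: float
    mean_f1: float | None
    mean_miss_rate: float | None
    mean_counting_accuracy: float | None


def match_boxes(
    truth: Sequence[Box], pred: Sequence[Box], iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy descending-IoU one-to-one matching; strict ``IoU > threshold``.

    Ties are broken by (truth index, prediction index), so the result is
    deterministic for any input order.
    """
    m = pairwise_iou(truth, pred)
    ti, pi = np.nonzero(m > iou_threshold)
    candidates = sorted(
        zip(m[ti, pi].tolist(), ti.tolist(), pi.tolist()),
        key=lambda c: (-c[0], c[1], c[2]),
    )
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for score, t, p in candidates:
        if t in used_t or p in used_p:
            continue
        used_t.add(t)
        used_p.add(p)
        pairs.append((t, p, score))
    return MatchResult(pairs=tuple(pairs), n_truth=len(truth), n_pred=len(pred))


def object_metrics(m: MatchResult) -> ObjectMetrics:
    """Precision, recall and F1 from a match; degenerate inputs give nulls."""
    if m.n_truth == 0 and m.n_pred == 0:
        warnings.warn("no truths and no predictions: object metrics undefined")
        return ObjectMetrics(None, None, None)
    precision = None if m.n_pred == 0 else m.tp / m.n_pred
    recall = None if m.n_truth == 0 else m.tp / m.n_truth
    p, r = precision or 0.0, recall or 0.0
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return ObjectMetrics(precision, recall, f1)


def image_metrics(true_count: int, automatic_count: int, missed: int) -> ImageMetrics:
    """Counting error/accuracy and miss rate for one image."""
    if missed < 0 or automatic_count < 0:
        raise ValueError("counts must be non-negative")
    if true_count < 1:
        warnings.warn("image has no true objects: image metrics undefined")
        return ImageMetrics(None, None, None, true_count, automatic_count)
    if missed > true_count:
        raise ValueError(f"missed ({missed}) exceeds true count ({true_count})")
    tc, ac = true_count, automatic_count
    return ImageMetrics(
        counting_error=(tc - ac) / tc,
        counting_accuracy=1.0 - abs(tc - ac) / tc,
        miss_rate=missed / tc,
        true_count=tc,
        automatic_count=ac,
    )


def r_squared(
    true_counts: Sequence[float],
    predicted_counts: Sequence[float],
    method: str = "pearson",
) -> float | None:
    """Agreement between predicted and true per-image counts.

    ``method="pearson"`` (default) is the squared Pearson correlation, the
    usual quantity annotated on count scatter plots; ``method="identity"`` is
    the coefficient of determination around the identity line y = x.
    """
    t = np.asarray(true_counts, dtype=float)
    p = np.asarray(predicted_counts, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    if np.ptp(t) == 0:
        warnings.warn("true counts are constant: r^2 undefined")
        return None
    if method == "pearson":
        if np.ptp(p) == 0:
            warnings.warn("predicted counts are constant: r^2 undefined")
            return None
        return float(stats.pearsonr(t, p).statistic ** 2)
    if method == "identity":
        ss_res = float(np.sum((t - p) ** 2))
        ss_tot = float(np.sum((t - t.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown method {method!r}")


def threshold_sweep(
    samples: Sequence[tuple[Sequence[Box], Sequence[Box]]],
    iou_threshold: float = 0.5,
    tau_min: float = 0.3,
    tau_max: float = 0.7,
    step: float = 0.05,
) -> tuple[list[SweepRow], float]:
    """Re-evaluate a test set over a grid of confidence thresholds.

    ``samples`` holds per-image (truth boxes, *unthresholded* predicted boxes)
    pairs.  For each grid threshold the confidence filter, matching and
    metrics are recomputed; per-image metrics are aggregated by unweighted
    mean.  Returns the rows and the threshold maximizing mean F1 (ties go to
    the smaller threshold).
    """
    if not samples:
        raise ValueError("empty test set")
    n_steps = int(round((tau_max - tau_min) / step))
    taus = [round(tau_min + i * step, 10) for i in range(n_steps + 1)]
    rows: list[SweepRow] = []
    for tau in taus:
        f1s, misses, accs = [], [], []
        for truth, preds in samples:
            kept = filter_confidence(preds, tau)
            m = match_boxes(truth, kept, iou_threshold)
            om = object_metrics(m)
            if om.f1 is not None:
                f1s.append(om.f1)
            if len(truth) > 0:
                im = image_metrics(len(truth), len(kept), m.missed)
                misses.append(im.miss_rate)
                accs.append(im.counting_accuracy)
        rows.append(
            SweepRow(
                tau=tau,
                mean_f1=float(np.mean(f1s)) if f1s else None,
                mean_miss_rate=float(np.mean(misses)) if misses else None,
                mean_counting_accuracy=float(np.mean(accs)) if accs else None,
            )
        )
    best = rows[0]
    for row in rows[1:]:
        if (row.mean_f1 or -1.0) > (best.mean_f1 or -1.0):
            best = row
    return rows, best.tau
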
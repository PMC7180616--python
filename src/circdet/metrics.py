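"""Detection evaluation: matching, recall/precision/F1, AP, paired tests.

Matching follows the VOC convention: detections are processed in
non-increasing confidence order; each claims the unmatched ground truth with
the highest IoU provided it reaches the IoU threshold (true positive,
ground truth consumed), otherwise it is a false positive.  Ground truths
never claimed are false negatives.

Average precision uses all-point interpolation: the precision-recall curve
is swept over every distinct confidence, the precision envelope
``p_interp(r) = max over recalls >= r of measured precision`` is taken, and
AP is the area ``sum_n (r_{n+1} - r_n) * p_interp(r_{n+1})``.

The paired comparison protocol resamples fixed-size image subsets from the
test set, computes AP per subset for each detector, and applies the
two-sided Wilcoxon signed-rank test at alpha = 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .nms import Detection, box_iou

__all__ = [
    "MatchResult",
    "PRCurve",
    "match_detections",
    "prf_at_threshold",
    "pr_curve",
    "average_precision",
    "detector_ap",
    "pooled_pr_curve",
    "subsample_ap",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
]

logger = logging.getLogger(__name__)

DEFAULT_IOU_THRESHOLD = 0.5


@dataclass(frozen=True)
class MatchResult:
    """Per-detection TP/FP labels (confidence-sorted order) and aggregate counts."""

    labels: tuple[bool, ...]        # True = TP, aligned with `order`
    order: tuple[int, ...]          # original detection indices, confidence desc
    gt_matched: tuple[bool, ...]
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points from a confidence sweep, plus the envelope."""

    recalls: tuple[float, ...]
    precisions: tuple[float, ...]
    thresholds: tuple[float, ...]

    def interpolated(self, r: float) -> float:
        best = 0.0
        for rr, pp in zip(self.recalls, self.precisions):
            if rr >= r:
                best = max(best, pp)
        return best


def _gt_box(g):
    return g.box if hasattr(g, "box") else g


def match_detections(dets, gts, iou_thresh: float = DEFAULT_IOU_THRESHOLD) -> MatchResult:
    """Greedy highest-confidence-first matching of detections to ground truths."""
    gt_boxes = [_gt_box(g) for g in gts]
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    matched = [False] * len(gt_boxes)
    labels: list[bool] = []
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, gb in enumerate(gt_boxes):
            if matched[j]:
                continue
            iou = box_iou(dets[i].box, gb)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_thresh:
            matched[best_j] = True
            labels.append(True)
        else:
            labels.append(False)
    tp = sum(labels)
    return MatchResult(
        labels=tuple(labels),
        order=tuple(order),
        gt_matched=tuple(matched),
        tp=tp,
        fp=len(labels) - tp,
        fn=len(gt_boxes) - tp,
    )


def prf_at_threshold(
    dets, gts, conf_thresh: float = 0.0, iou_thresh: float = DEFAULT_IOU_THRESHOLD
) -> tuple[float, float, float]:
    """Recall, precision and F1 after filtering detections by confidence.

    Degenerate cases are reported as 0 with a warning: precision with no
    surviving detections, F1 when recall + precision is 0.  An empty
    ground-truth list makes recall undefined and raises.
    """
    if len(gts) == 0:
        raise ValueError("recall is undefined with no ground truths")
    kept = [d for d in dets if d.confidence >= conf_thresh]
    m = match_detections(kept, gts, iou_thresh)
    recall = m.tp / (m.tp + m.fn)
    if m.tp + m.fp == 0:
        logger.warning("no detections above confidence %.3g; precision reported as 0", conf_thresh)
        precision = 0.0
    else:
        precision = m.tp / (m.tp + m.fp)
    f1 = 0.0 if recall + precision == 0 else 2 * recall * precision / (recall + precision)
    return recall, precision, f1


def pr_curve(dets, gts, iou_thresh: float = DEFAULT_IOU_THRESHOLD) -> PRCurve:
    """Sweep the confidence threshold over all distinct confidences.

    Greedy matching has the prefix property — the matches of the top-k
    detections do not depend on lower-ranked ones — so one global match in
    confidence order yields every threshold's counts by cumulative sums.
    """
    n_gt = len(gts)
    m = match_detections(dets, gts, iou_thresh)
    confs = [dets[i].confidence for i in m.order]
    recalls, precisions, thresholds = [], [], []
    tp = fp = 0
    for idx, (is_tp, c) in enumerate(zip(m.labels, confs)):
        if is_tp:
            tp += 1
        else:
            fp += 1
        last_of_threshold = idx == len(confs) - 1 or confs[idx + 1] < c
        if last_of_threshold:
            recalls.append(tp / n_gt if n_gt else 0.0)
            precisions.append(tp / (tp + fp))
            thresholds.append(c)
    return PRCurve(tuple(recalls), tuple(precisions), tuple(thresholds))


def average_precision(curve: PRCurve) -> float:
    """All-point interpolated AP from a precision-recall curve."""
    if len(curve.recalls) == 0:
        logger.warning("empty precision-recall curve; AP reported as 0")
        return 0.0
    ap = 0.0
    prev_r = 0.0
    # recalls are non-decreasing along the sweep; envelope is max precision at >= r
    for r in sorted(set(curve.recalls)):
        if r > prev_r:
            ap += (r - prev_r) * curve.interpolated(r)
            prev_r = r
    return ap


def detector_ap(dets, gts, iou_thresh: float = DEFAULT_IOU_THRESHOLD) -> float:
    """Convenience: AP of a detection list against ground truths."""
    return average_precision(pr_curve(dets, gts, iou_thresh))


def pooled_pr_curve(
    dets_by_image: dict, gts_by_image: dict, iou_thresh: float = DEFAULT_IOU_THRESHOLD
) -> PRCurve:
    """Precision-recall curve over a multi-image set.

    Matching is per image (a detection can only claim ground truth in its
    own image); the confidence sweep pools all detections' (confidence,
    TP/FP) labels against the total ground-truth count.
    """
    labeled: list[tuple[float, bool]] = []
    n_gt = 0
    for img, gts in gts_by_image.items():
        n_gt += len(gts)
        dets = dets_by_image.get(img, [])
        m = match_detections(dets, gts, iou_thresh)
        for i, is_tp in zip(m.order, m.labels):
            labeled.append((dets[i].confidence, is_tp))
    for img, dets in dets_by_image.items():
        if img not in gts_by_image:
            labeled.extend((d.confidence, False) for d in dets)
    labeled.sort(key=lambda t: -t[0])
    recalls, precisions, thresholds = [], [], []
    tp = fp = 0
    for idx, (c, is_tp) in enumerate(labeled):
        if is_tp:
            tp += 1
        else:
            fp += 1
        if idx == len(labeled) - 1 or labeled[idx + 1][0] < c:
            recalls.append(tp / n_gt if n_gt else 0.0)
            precisions.append(tp / (tp + fp))
            thresholds.append(c)
    return PRCurve(tuple(recalls), tuple(precisions), tuple(thresholds))


def subsample_ap(
    dets_by_image: dict,
    gts_by_image: dict,
    n_subsets: int = 30,
    subset_size: int = 80,
    seed: int = 0,
    iou_thresh: float = DEFAULT_IOU_THRESHOLD,
) -> list[float]:
    """AP over repeated random image subsets of the test set.

    Each subset draws ``subset_size`` image ids without replacement;
    subsets are drawn independently of each other.  Deterministic given
    ``seed``.
    """
    images = sorted(gts_by_image)
    if len(images) < subset_size:
        raise ValueError(f"need at least {subset_size} images, have {len(images)}")
    rng = np.random.default_rng(seed)
    aps = []
    for _ in range(n_subsets):
        chosen = rng.choice(len(images), size=subset_size, replace=False)
        sub_imgs = [images[ci] for ci in chosen]
        curve = pooled_pr_curve(
            {img: dets_by_image.get(img, []) for img in sub_imgs},
            {img: gts_by_image[img] for img in sub_imgs},
            iou_thresh,
        )
        aps.append(average_precision(curve))
    return aps


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float        # W+ (sum of ranks of positive differences)
    p_value: float
    n_effective: int
    method: str             # "exact" or "normal"
    degenerate: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


def wilcoxon_signed_rank(ap_a, ap_b, exact_max_n: int = 12) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties get mid-ranks.  The null distribution
    of W+ is enumerated exactly (2^n sign patterns) for up to
    ``exact_max_n`` effective pairs; beyond that, a normal approximation
    with continuity correction and a mid-rank tie variance correction is
    used.  All-zero differences give p = 1, flagged degenerate.
    """
    a = np.asarray(ap_a, dtype=float)
    b = np.asarray(ap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        logger.warning("all paired differences are zero; Wilcoxon p-value reported as 1")
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0,
                              method="exact", degenerate=True)
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        # exact two-sided p by enumerating all 2^n sign assignments
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        mu = n * (n + 1) / 4.0
        dev = abs(w_plus - mu)
        p = float(np.mean(np.abs(sums - mu) >= dev - 1e-12))
        return WilcoxonResult(w_plus, min(p, 1.0), n, "exact")

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups of |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, "normal", degenerate=True)
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
    p = math.erfc(max(z, 0.0) / math.sqrt(2.0))
    return WilcoxonResult(w_plus, min(p, 1.0), n, "normal")


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
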
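"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: circle
areas come from Monte-Carlo sampling or shapely polygon approximation, NMS
and matching from naive O(n^2) re-implementations, AP from exhaustive
threshold enumeration.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from circdet.geometry import CircleBox
from circdet.nms import Detection, box_iou


# ---------------------------------------------------------------- geometry

def mc_overlap_area(a: CircleBox, b: CircleBox, n: int = 1_000_000, seed: int = 0):
    """Monte-Carlo lens area over the bounding square of the two circles.

    Returns (estimate, standard_error).
    """
    rng = np.random.default_rng(seed)
    x0 = min(a.cx - a.r, b.cx - b.r)
    x1 = max(a.cx + a.r, b.cx + b.r)
    y0 = min(a.cy - a.r, b.cy - b.r)
    y1 = max(a.cy + a.r, b.cy + b.r)
    sq = (x1 - x0) * (y1 - y0)
    xs = rng.uniform(x0, x1, n)
    ys = rng.uniform(y0, y1, n)
    inside = ((xs - a.cx) ** 2 + (ys - a.cy) ** 2 <= a.r**2) & (
        (xs - b.cx) ** 2 + (ys - b.cy) ** 2 <= b.r**2
    )
    p = inside.mean()
    return p * sq, math.sqrt(p * (1 - p) / n) * sq


def shapely_circle_iou(a: CircleBox, b: CircleBox) -> float:
    """Polygonal-approximation IoU via shapely buffers (256 segments)."""
    from shapely.geometry import Point

    pa = Point(a.cx, a.cy).buffer(a.r, quad_segs=64)
    pb = Point(b.cx, b.cy).buffer(b.r, quad_segs=64)
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union > 0 else 0.0


def random_circle_pair(rng, regime: str | None = None) -> tuple[CircleBox, CircleBox]:
    """A random circle pair, optionally forced into a named IoU regime."""
    R = rng.uniform(2.0, 50.0)
    r = rng.uniform(2.0, 50.0)
    R, r = max(R, r), min(R, r)
    if regime == "disjoint":
        d = (R + r) * rng.uniform(1.01, 2.0)
    elif regime == "containment":
        d = (R - r) * rng.uniform(0.0, 0.95)
    elif regime == "lens":
        d = rng.uniform(R - r + 1e-3, R + r - 1e-3)
    else:
        d = rng.uniform(0.0, (R + r) * 1.3)
    ang = rng.uniform(0, 2 * math.pi)
    cx, cy = rng.uniform(-100, 100, 2)
    return (
        CircleBox(cx, cy, R),
        CircleBox(cx + d * math.cos(ang), cy + d * math.sin(ang), r),
    )


# --------------------------------------------------------------------- nms

def brute_force_nms(dets: list[Detection], lam: float) -> list[Detection]:
    """Naive list-scan NMS: repeatedly take the argmax and drop overlaps."""
    remaining = list(enumerate(dets))
    kept = []
    while remaining:
        best = min(remaining, key=lambda t: (-t[1].confidence, t[0]))
        kept.append(best[1])
        remaining = [
            (i, d)
            for i, d in remaining
            if i != best[0] and box_iou(best[1].box, d.box) < lam
        ]
    return kept


def random_detections(rng, n: int, extent: float = 100.0) -> list[Detection]:
    dets = []
    for _ in range(n):
        dets.append(
            Detection(
                box=CircleBox(rng.uniform(0, extent), rng.uniform(0, extent), rng.uniform(2, 20)),
                confidence=round(float(rng.uniform(0.05, 1.0)), 3),  # rounding forces ties
            )
        )
    return dets


# ----------------------------------------------------------------- metrics

def brute_force_match(dets, gts, iou_thresh):
    """Independent greedy matcher; returns (tp, fp, fn, labels in conf order)."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    free = set(range(len(gts)))
    labels = []
    for i in order:
        cand = [(box_iou(dets[i].box, gts[j].box if hasattr(gts[j], "box") else gts[j]), j)
                for j in free]
        cand = [c for c in cand if c[0] >= iou_thresh]
        if cand:
            best = max(cand, key=lambda c: c[0])
            free.discard(best[1])
            labels.append(True)
        else:
            labels.append(False)
    tp = sum(labels)
    return tp, len(labels) - tp, len(gts) - tp, labels


def enumerate_ap(dets, gts, iou_thresh=0.5):
    """AP by explicit enumeration of every confidence threshold.

    Computes (recall, precision) at each distinct confidence cutoff by
    re-matching the filtered list from scratch, then integrates the
    interpolated envelope over recall.
    """
    confs = sorted({d.confidence for d in dets}, reverse=True)
    points = []
    for c in confs:
        kept = [d for d in dets if d.confidence >= c]
        tp, fp, fn, _ = brute_force_match(kept, gts, iou_thresh)
        points.append((tp / len(gts), tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for r in sorted({p[0] for p in points}):
        if r <= prev_r:
            continue
        p_int = max(pp for rr, pp in points if rr >= r)
        ap += (r - prev_r) * p_int
        prev_r = r
    return ap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
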
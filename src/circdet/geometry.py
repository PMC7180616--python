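"""Circle and rectangle bounding-box geometry.

Circular bounding boxes (C-Bboxes) localize a quasi-circular object by its
center and radius.  The exact intersection area of two circles is a lens
whose area has a closed form in the two half-angles subtended by the chord
through the intersection points; the IoU follows from
``A / (pi R^2 + pi r^2 - A)`` and collapses to ``(r/R)^2`` when the smaller
circle is contained in the larger.

Coordinates are continuous pixels, origin at the image top-left, y down.
No integer snapping happens anywhere in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "CircleBox",
    "RectBox",
    "RectToCircleMode",
    "circle_overlap_area",
    "circle_iou",
    "rect_iou",
    "rect_to_circle",
    "circle_to_rect",
]


@dataclass(frozen=True)
class CircleBox:
    """A circular bounding box: center ``(cx, cy)`` and radius ``r``, in pixels."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cx) and math.isfinite(self.cy) and math.isfinite(self.r)):
            raise ValueError("circle coordinates must be finite")
        if self.r < 0:
            raise ValueError(f"radius must be non-negative, got {self.r}")

    @property
    def area(self) -> float:
        return math.pi * self.r * self.r


@dataclass(frozen=True)
class RectBox:
    """An axis-aligned rectangle in center format: ``(cx, cy, w, h)``, in pixels."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for v in (self.cx, self.cy, self.w, self.h):
            if not math.isfinite(v):
                raise ValueError("rect coordinates must be finite")
        if self.w < 0 or self.h < 0:
            raise ValueError("rect width/height must be non-negative")

    @property
    def area(self) -> float:
        return self.w * self.h


class RectToCircleMode(str, Enum):
    MEAN = "mean"
    MIN = "min"
    MAX = "max"
    CIRCUMSCRIBED = "circumscribed"


def _clamp(x: float, lo: float = -1.0, hi: float = 1.0) -> float:
    # arccos arguments drift out of [-1, 1] near tangency; clamp absorbs it
    return lo if x < lo else hi if x > hi else x


def circle_overlap_area(a: CircleBox, b: CircleBox) -> float:
    """Exact intersection area of two circles.

    Three regimes, split by the center distance d against the radii R, r:

    * ``d >= R + r``      : disjoint (or externally tangent), area 0;
    * ``d < |R - r|``     : containment, area ``pi * min(R, r)^2``;
    * otherwise           : lens, ``theta*R^2 + phi*r^2
      - R^2 sin(2 theta)/2 - r^2 sin(2 phi)/2`` with
      ``theta = arccos((R^2 + d^2 - r^2) / (2 R d))`` and
      ``phi   = arccos((r^2 + d^2 - R^2) / (2 r d))``.
    """
    R, r = a.r, b.r
    d = math.hypot(a.cx - b.cx, a.cy - b.cy)
    if d >= R + r:
        return 0.0
    if d < abs(R - r):
        m = min(R, r)
        return math.pi * m * m
    if R == 0.0 or r == 0.0:
        return 0.0
    # lens regime; d > 0 here because d >= |R - r| rules out d == 0 unless R == r,
    # and R == r with d == 0 falls into containment only when d < 0, impossible —
    # guard the d == 0, R == r coincidence explicitly.
    if d == 0.0:
        m = min(R, r)
        return math.pi * m * m
    theta = math.acos(_clamp((R * R + d * d - r * r) / (2.0 * R * d)))
    phi = math.acos(_clamp((r * r + d * d - R * R) / (2.0 * r * d)))
    area = (
        theta * R * R
        + phi * r * r
        - 0.5 * R * R * math.sin(2.0 * theta)
        - 0.5 * r * r * math.sin(2.0 * phi)
    )
    return max(area, 0.0)


def circle_iou(a: CircleBox, b: CircleBox) -> float:
    """Intersection-over-union of two circles, in [0, 1].

    Containment reduces to ``(min(R,r) / max(R,r))^2``; degenerate circles
    (zero union area) are defined to have IoU 0 so NMS stays total.
    """
    if a.r == 0.0 and b.r == 0.0:
        return 0.0
    inter = circle_overlap_area(a, b)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return min(inter / union, 1.0)


def rect_iou(a: RectBox, b: RectBox) -> float:
    """Standard IoU of two axis-aligned rectangles in center format."""
    ix = min(a.cx + a.w / 2, b.cx + b.w / 2) - max(a.cx - a.w / 2, b.cx - b.w / 2)
    iy = min(a.cy + a.h / 2, b.cy + b.h / 2) - max(a.cy - a.h / 2, b.cy - b.h / 2)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return min(inter / union, 1.0)


def rect_to_circle(rect: RectBox, mode: RectToCircleMode | str = RectToCircleMode.MEAN) -> CircleBox:
    """Derive a circle from a rectangle, preserving the center.

    Modes: ``mean`` r=(w+h)/4 (default), ``min`` r=min(w,h)/2,
    ``max`` r=max(w,h)/2, ``circumscribed`` r=sqrt(w^2+h^2)/2.
    """
    mode = RectToCircleMode(mode)
    if mode is RectToCircleMode.MEAN:
        r = (rect.w + rect.h) / 4.0
    elif mode is RectToCircleMode.MIN:
        r = min(rect.w, rect.h) / 2.0
    elif mode is RectToCircleMode.MAX:
        r = max(rect.w, rect.h) / 2.0
    else:
        r = math.hypot(rect.w, rect.h) / 2.0
    return CircleBox(rect.cx, rect.cy, r)


def circle_to_rect(c: CircleBox) -> RectBox:
    """Tight enclosing square of a circle (w = h = 2r, same center)."""
    return RectBox(c.cx, c.cy, 2.0 * c.r, 2.0 * c.r)
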
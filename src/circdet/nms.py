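"""Greedy non-maximum suppression over circular or rectangular detections.

Repeatedly pick the highest-confidence remaining detection, emit it, and
delete every remaining detection whose IoU with it is >= the threshold.
Ties on confidence break toward the lower original input index so the
result is a deterministic function of the detection set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .geometry import CircleBox, RectBox, circle_iou, rect_iou

__all__ = ["Detection", "nms", "box_iou"]

DEFAULT_NMS_THRESHOLD = 0.5


@dataclass(frozen=True)
class Detection:
    """A detected box plus objectness confidence and per-class probabilities."""

    box: CircleBox | RectBox
    confidence: float
    class_probs: tuple[float, ...] = field(default=(1.0,))

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        object.__setattr__(self, "class_probs", tuple(self.class_probs))
        if any(not 0.0 <= p <= 1.0 for p in self.class_probs):
            raise ValueError("class probabilities must be in [0, 1]")

    @property
    def class_id(self) -> int:
        return max(range(len(self.class_probs)), key=self.class_probs.__getitem__)


def box_iou(a: CircleBox | RectBox, b: CircleBox | RectBox) -> float:
    """IoU dispatched on box geometry; mixing circle and rect is an error."""
    if isinstance(a, CircleBox) and isinstance(b, CircleBox):
        return circle_iou(a, b)
    if isinstance(a, RectBox) and isinstance(b, RectBox):
        return rect_iou(a, b)
    raise TypeError(f"cannot compute IoU between {type(a).__name__} and {type(b).__name__}")


def nms(
    detections: Sequence[Detection],
    lambda_nms: float = DEFAULT_NMS_THRESHOLD,
    *,
    per_class: bool = False,
) -> list[Detection]:
    """Greedy NMS; returns kept detections in non-increasing confidence order.

    Suppression uses ``IoU >= lambda_nms`` (with >=).  ``per_class=True``
    restricts suppression to detections of the same argmax class; the
    default is class-agnostic, which is the right choice for a
    single-class task.
    """
    if not 0.0 <= lambda_nms <= 1.0:
        raise ValueError(f"lambda_nms must be in [0, 1], got {lambda_nms}")
    if not detections:
        return []
    kinds = {type(d.box) for d in detections}
    if len(kinds) > 1:
        raise TypeError("all detections must share one box geometry type")

    # (confidence desc, original index asc) is a total order
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    alive = [True] * len(detections)
    kept: list[Detection] = []
    for pos, i in enumerate(order):
        if not alive[i]:
            continue
        det = detections[i]
        kept.append(det)
        alive[i] = False
        for j in order[pos + 1 :]:
            if not alive[j]:
                continue
            other = detections[j]
            if per_class and other.class_id != det.class_id:
                continue
            if box_iou(det.box, other.box) >= lambda_nms:
                alive[j] = False
    return kept
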
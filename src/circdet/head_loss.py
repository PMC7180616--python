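"""Circular-box prediction head: decoding, encoding, targets, and the loss.

A detection head predicts, per grid cell and per prior anchor, three raw
coordinates (tx, ty, tr), a raw objectness score and raw class scores.
Decoding maps them to image space:

    x_hat = (sigmoid(tx) + cx) * stride        [pixels]
    y_hat = (sigmoid(ty) + cy) * stride        [pixels]
    r_hat = pr * exp(tr)                       [pixels]

where (cx, cy) is the cell offset from the image top-left and pr the prior
anchor radius.  Confidence and class probabilities are sigmoids of their raw
scores.

The loss is a sum of five terms over an S x S grid with B anchors per cell:
weighted squared error on the decoded center (grid units) and radius
(pixels) at object slots, binary cross-entropy on confidence at object and
no-object slots (the latter down-weighted), and per-class binary
cross-entropy at object slots.  Default weights are lambda_coord = 5 and
lambda_noobj = 0.5, which counteract the object/no-object imbalance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .anchors import AnchorSet, concentric_iou
from .geometry import CircleBox
from .nms import Detection

__all__ = [
    "HeadOutput",
    "TargetTensor",
    "LossBreakdown",
    "decode",
    "encode",
    "assign_targets",
    "total_loss",
    "total_loss_grad",
    "DEFAULT_STRIDES",
]

logger = logging.getLogger(__name__)

DEFAULT_STRIDES = (8, 16, 32)  # finest scale first, matching anchor scale groups
_EPS_PROB = 1e-7
_EPS_EDGE = 1e-6


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class HeadOutput:
    """Raw head tensor for one detection scale.

    Arrays are indexed ``[row, col, anchor]`` (row = cy cell index); class
    scores carry an extra trailing class axis.
    """

    grid_size: int
    anchors_per_cell: int
    t_x: np.ndarray
    t_y: np.ndarray
    t_r: np.ndarray
    t_conf: np.ndarray
    t_class: np.ndarray

    def __post_init__(self) -> None:
        S, B = self.grid_size, self.anchors_per_cell
        for name in ("t_x", "t_y", "t_r", "t_conf", "t_class"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape[:3] != (S, S, B):
                raise ValueError(f"{name} has shape {arr.shape}, expected leading ({S}, {S}, {B})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.t_class.ndim != 4:
            raise ValueError("t_class must have a trailing class axis")

    @property
    def n_classes(self) -> int:
        return self.t_class.shape[-1]

    @classmethod
    def zeros(cls, grid_size: int, anchors_per_cell: int, n_classes: int = 1) -> "HeadOutput":
        S, B = grid_size, anchors_per_cell
        return cls(S, B, np.zeros((S, S, B)), np.zeros((S, S, B)), np.zeros((S, S, B)),
                   np.zeros((S, S, B)), np.zeros((S, S, B, n_classes)))


@dataclass
class TargetTensor:
    """Regression/classification targets for one scale.

    ``obj_mask`` and ``noobj_mask`` are binary and mutually exclusive per
    slot.  ``x``, ``y`` are the target center in grid units, ``r`` the target
    radius in pixels; ``conf`` and ``class_probs`` the confidence and class
    targets.
    """

    obj_mask: np.ndarray
    noobj_mask: np.ndarray
    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    conf: np.ndarray
    class_probs: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.obj_mask != 0) & (self.obj_mask != 1)) or np.any(
            (self.noobj_mask != 0) & (self.noobj_mask != 1)
        ):
            raise ValueError("masks must be binary")
        if np.any(self.obj_mask * self.noobj_mask != 0):
            raise ValueError("obj and noobj masks must be mutually exclusive")

    @classmethod
    def empty(cls, grid_size: int, anchors_per_cell: int, n_classes: int = 1) -> "TargetTensor":
        S, B = grid_size, anchors_per_cell
        return cls(
            obj_mask=np.zeros((S, S, B)),
            noobj_mask=np.ones((S, S, B)),
            x=np.zeros((S, S, B)),
            y=np.zeros((S, S, B)),
            r=np.zeros((S, S, B)),
            conf=np.zeros((S, S, B)),
            class_probs=np.zeros((S, S, B, n_classes)),
        )


@dataclass(frozen=True)
class LossBreakdown:
    coord_xy: float
    coord_r: float
    conf_obj: float
    conf_noobj: float
    class_term: float
    lambda_coord: float
    lambda_noobj: float

    @property
    def total(self) -> float:
        return (
            self.lambda_coord * (self.coord_xy + self.coord_r)
            + self.conf_obj
            + self.lambda_noobj * self.conf_noobj
            + self.class_term
        )


def decode(
    head: HeadOutput,
    anchors: AnchorSet | np.ndarray,
    image_size: float,
    scale: int | None = None,
    conf_threshold: float = 0.0,
) -> list[Detection]:
    """Decode a raw head tensor into circular detections in pixel coordinates.

    ``anchors`` may be an :class:`AnchorSet` (then ``scale`` selects its
    group) or a plain array of prior radii for this scale.
    """
    if isinstance(anchors, AnchorSet):
        if anchors.shape != "circle":
            raise ValueError("decode requires circular anchors")
        prior = anchors.dims_for_scale(scale if scale is not None else 0)
    else:
        prior = np.asarray(anchors, dtype=float).reshape(-1)
    if len(prior) != head.anchors_per_cell:
        raise ValueError(
            f"anchor count {len(prior)} does not match anchors_per_cell {head.anchors_per_cell}"
        )
    S = head.grid_size
    stride = image_size / S
    cy, cx = np.meshgrid(np.arange(S), np.arange(S), indexing="ij")
    x_hat = (_sigmoid(head.t_x) + cx[:, :, None]) * stride
    y_hat = (_sigmoid(head.t_y) + cy[:, :, None]) * stride
    r_hat = prior[None, None, :] * np.exp(head.t_r)
    conf = _sigmoid(head.t_conf)
    cls = _sigmoid(head.t_class)

    out: list[Detection] = []
    for i in range(S):
        for j in range(S):
            for b in range(head.anchors_per_cell):
                if conf[i, j, b] < conf_threshold:
                    continue
                out.append(
                    Detection(
                        box=CircleBox(float(x_hat[i, j, b]), float(y_hat[i, j, b]), float(r_hat[i, j, b])),
                        confidence=float(conf[i, j, b]),
                        class_probs=tuple(float(p) for p in cls[i, j, b]),
                    )
                )
    return out


def encode(
    gt: CircleBox, anchor_radius: float, cell: tuple[int, int], stride: float
) -> tuple[float, float, float]:
    """Invert the decode map for one ground truth: returns (tx, ty, tr).

    ``cell`` is (row, col).  The ground-truth center must lie in the given
    cell; centers exactly on a cell edge are nudged inward by 1e-6 cell
    units to keep the logit finite.
    """
    row, col = cell
    fx = gt.cx / stride - col
    fy = gt.cy / stride - row
    if not (0.0 <= fx <= 1.0 and 0.0 <= fy <= 1.0):
        raise ValueError("ground-truth center does not lie in the given cell")
    fx = min(max(fx, _EPS_EDGE), 1.0 - _EPS_EDGE)
    fy = min(max(fy, _EPS_EDGE), 1.0 - _EPS_EDGE)
    if gt.r <= 0 or anchor_radius <= 0:
        raise ValueError("radius and anchor radius must be positive to encode")
    tx = math.log(fx / (1.0 - fx))
    ty = math.log(fy / (1.0 - fy))
    tr = math.log(gt.r / anchor_radius)
    return tx, ty, tr


def assign_targets(
    gts,
    anchors: AnchorSet,
    image_size: float,
    strides=DEFAULT_STRIDES,
    n_classes: int = 1,
) -> list[TargetTensor]:
    """Build per-scale target tensors from ground-truth circles.

    Each ground truth is owned by exactly one (scale, cell, anchor) slot:
    the anchor with the highest concentric IoU to its radius decides the
    scale, and the cell containing its center at that scale's stride decides
    the position.  If two ground truths collide on a slot the later one (by
    input order) wins and the earlier is demoted with a warning.
    """
    if anchors.shape != "circle":
        raise ValueError("target assignment requires circular anchors")
    targets = []
    for s, stride in enumerate(strides):
        S = int(round(image_size / stride))
        B = len(anchors.scale_assignment[s])
        targets.append(TargetTensor.empty(S, B, n_classes))

    all_radii = anchors.dims  # sorted ascending; scale_assignment indexes into it
    anchor_scale = {}
    for s, group in enumerate(anchors.scale_assignment):
        for pos, idx in enumerate(group):
            anchor_scale[idx] = (s, pos)

    for gt in gts:
        box = gt.box if hasattr(gt, "box") else gt
        class_id = getattr(gt, "class_id", 0)
        if not (0 <= box.cx < image_size and 0 <= box.cy < image_size):
            raise ValueError("ground truth lies outside the image")
        ious = [concentric_iou(box.r, pr, "circle") for pr in all_radii]
        best = int(np.argmax(ious))
        s, b = anchor_scale[best]
        stride = strides[s]
        tgt = targets[s]
        S = tgt.obj_mask.shape[0]
        col = min(int(box.cx / stride), S - 1)
        row = min(int(box.cy / stride), S - 1)
        if tgt.obj_mask[row, col, b] == 1:
            logger.warning(
                "target collision at scale %d cell (%d, %d) anchor %d: "
                "earlier ground truth demoted", s, row, col, b,
            )
        tgt.obj_mask[row, col, b] = 1
        tgt.noobj_mask[row, col, b] = 0
        tgt.x[row, col, b] = box.cx / stride
        tgt.y[row, col, b] = box.cy / stride
        tgt.r[row, col, b] = box.r
        tgt.conf[row, col, b] = 1.0
        tgt.class_probs[row, col, b, :] = 0.0
        tgt.class_probs[row, col, b, class_id] = 1.0
    return targets


def _decoded_quantities(head: HeadOutput, prior: np.ndarray):
    S = head.grid_size
    cy, cx = np.meshgrid(np.arange(S), np.arange(S), indexing="ij")
    x_hat = _sigmoid(head.t_x) + cx[:, :, None]  # grid units
    y_hat = _sigmoid(head.t_y) + cy[:, :, None]
    r_hat = prior[None, None, :] * np.exp(head.t_r)  # pixels
    c_hat = np.clip(_sigmoid(head.t_conf), _EPS_PROB, 1.0 - _EPS_PROB)
    p_hat = np.clip(_sigmoid(head.t_class), _EPS_PROB, 1.0 - _EPS_PROB)
    return x_hat, y_hat, r_hat, c_hat, p_hat


def _check_pair(heads, targets, anchors):
    if isinstance(heads, HeadOutput):
        heads = [heads]
    if isinstance(targets, TargetTensor):
        targets = [targets]
    if len(heads) != len(targets):
        raise ValueError("one target tensor per head scale required")
    priors = []
    for s, (h, t) in enumerate(zip(heads, targets)):
        if isinstance(anchors, AnchorSet):
            prior = anchors.dims_for_scale(s)
        else:
            prior = np.asarray(anchors[s] if isinstance(anchors, (list, tuple)) else anchors, float).reshape(-1)
        if len(prior) != h.anchors_per_cell:
            raise ValueError("anchor group size does not match head anchors_per_cell")
        if t.obj_mask.shape != h.t_x.shape:
            raise ValueError("target tensor shape does not match head shape")
        priors.append(prior)
    return heads, targets, priors


def total_loss(
    heads,
    targets,
    anchors,
    lambda_coord: float = 5.0,
    lambda_noobj: float = 0.5,
) -> LossBreakdown:
    """Evaluate the five-term detection loss over one or more scales.

    ``heads``/``targets`` are per-scale lists (or single instances);
    ``anchors`` an :class:`AnchorSet` or per-scale radius arrays.  The
    coordinate terms compare decoded centers in grid units and decoded radii
    in pixels; probabilities are clipped to [1e-7, 1 - 1e-7] before logs.
    """
    heads, targets, priors = _check_pair(heads, targets, anchors)
    coord_xy = coord_r = conf_obj = conf_noobj = class_term = 0.0
    for h, t, prior in zip(heads, targets, priors):
        x_hat, y_hat, r_hat, c_hat, p_hat = _decoded_quantities(h, prior)
        obj, noobj = t.obj_mask, t.noobj_mask
        coord_xy += float(np.sum(obj * ((t.x - x_hat) ** 2 + (t.y - y_hat) ** 2)))
        coord_r += float(np.sum(obj * (t.r - r_hat) ** 2))
        conf_obj += float(np.sum(obj * (-t.conf * np.log(c_hat))))
        conf_noobj += float(np.sum(noobj * (-(1.0 - t.conf) * np.log(1.0 - c_hat))))
        class_term += float(
            np.sum(
                obj[..., None]
                * (-t.class_probs * np.log(p_hat) - (1.0 - t.class_probs) * np.log(1.0 - p_hat))
            )
        )
    return LossBreakdown(coord_xy, coord_r, conf_obj, conf_noobj, class_term,
                         lambda_coord, lambda_noobj)


def total_loss_grad(heads, targets, anchors, lambda_coord: float = 5.0, lambda_noobj: float = 0.5):
    """Analytic gradient of :func:`total_loss` w.r.t. every raw head value.

    Returns a list (per scale) of dicts with keys ``t_x, t_y, t_r, t_conf,
    t_class`` holding arrays shaped like the head tensors.  Used to validate
    the sigmoid/exp decode chain against finite differences.
    """
    heads, targets, priors = _check_pair(heads, targets, anchors)
    out = []
    for h, t, prior in zip(heads, targets, priors):
        x_hat, y_hat, r_hat, c_hat, p_hat = _decoded_quantities(h, prior)
        obj, noobj = t.obj_mask, t.noobj_mask
        sx = _sigmoid(h.t_x)
        sy = _sigmoid(h.t_y)
        g_tx = lambda_coord * obj * 2.0 * (x_hat - t.x) * sx * (1.0 - sx)
        g_ty = lambda_coord * obj * 2.0 * (y_hat - t.y) * sy * (1.0 - sy)
        g_tr = lambda_coord * obj * 2.0 * (r_hat - t.r) * r_hat
        # d/dt of -C log(sigma(t)) is C (sigma - 1); of -(1-C) log(1-sigma) is (1-C) sigma
        g_tc = obj * t.conf * (c_hat - 1.0) + lambda_noobj * noobj * (1.0 - t.conf) * c_hat
        g_tp = obj[..., None] * (p_hat - t.class_probs)
        out.append({"t_x": g_tx, "t_y": g_ty, "t_r": g_tr, "t_conf": g_tc, "t_class": g_tp})
    return out
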
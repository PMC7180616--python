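"""Prior-anchor clustering of ground-truth box dimensions under IoU distance.

Anchors are the reference dimensions a detector regresses from.  Following
the YOLOv2 recipe, they are obtained by k-means over the training-set box
dimensions with ``1 - IoU`` of concentrically placed boxes as the distance,
so that big and small boxes contribute comparably.  For circles the
concentric IoU is simply ``(min(r, r') / max(r, r'))^2``; for rectangles it
is the usual area ratio of the concentric overlap.

The quality diagnostic is the average best IoU: the mean over ground truths
of the best concentric IoU achievable with any anchor.  Plotted against k it
gives the familiar monotone saturation curve used to choose the number of
anchors (nine here, split three per detection scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnchorSet",
    "iou_distance",
    "concentric_iou",
    "kmeans_anchors",
    "average_best_iou",
]


@dataclass(frozen=True)
class AnchorSet:
    """k anchor dimensions, sorted ascending by area, split into 3 scale groups.

    ``dims`` has shape (k,) of radii for ``shape == "circle"`` or (k, 2) of
    (w, h) for ``shape == "rect"``.  ``scale_assignment`` partitions indices
    into three groups, smallest areas first; group 0 belongs to the
    finest-resolution detection scale.
    """

    shape: str
    dims: np.ndarray
    scale_assignment: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "rect"):
            raise ValueError(f"shape must be 'circle' or 'rect', got {self.shape!r}")
        dims = np.asarray(self.dims, dtype=float)
        object.__setattr__(self, "dims", dims)
        if dims.ndim != (1 if self.shape == "circle" else 2):
            raise ValueError("dims shape inconsistent with anchor geometry")
        areas = _areas(dims, self.shape)
        if np.any(np.diff(areas) < 0):
            raise ValueError("anchor dims must be sorted ascending by area")
        k = len(dims)
        flat = [i for g in self.scale_assignment for i in g]
        if sorted(flat) != list(range(k)):
            raise ValueError("scale_assignment must partition the anchor indices")

    @property
    def k(self) -> int:
        return len(self.dims)

    def dims_for_scale(self, scale: int) -> np.ndarray:
        return self.dims[list(self.scale_assignment[scale])]


def _areas(dims: np.ndarray, shape: str) -> np.ndarray:
    if shape == "circle":
        return np.pi * np.asarray(dims, float) ** 2
    d = np.asarray(dims, float)
    return d[..., 0] * d[..., 1]


def concentric_iou(dim_a, dim_b, shape: str) -> float:
    """IoU of two boxes placed at the same center, from their dimensions only."""
    if shape == "circle":
        a = np.asarray(dim_a, float).reshape(1)
        b = np.asarray(dim_b, float).reshape(1)
    else:
        a = np.asarray(dim_a, float).reshape(1, 2)
        b = np.asarray(dim_b, float).reshape(1, 2)
    return float(_concentric_iou_matrix(a, b, shape)[0, 0])


def _concentric_iou_matrix(a: np.ndarray, b: np.ndarray, shape: str) -> np.ndarray:
    """Pairwise concentric IoU, a: (n, d), b: (m, d) -> (n, m)."""
    if shape == "circle":
        ra = a.reshape(-1, 1)
        rb = b.reshape(1, -1)
        lo = np.minimum(ra, rb)
        hi = np.maximum(ra, rb)
        with np.errstate(divide="ignore", invalid="ignore"):
            iou = np.where(hi > 0, (lo / np.where(hi > 0, hi, 1.0)) ** 2, 0.0)
        return iou
    wa, ha = a[:, 0:1], a[:, 1:2]
    wb, hb = b[None, :, 0], b[None, :, 1]
    inter = np.minimum(wa, wb) * np.minimum(ha, hb)
    union = wa * ha + wb * hb - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)


def iou_distance(dim_a, dim_b, shape: str) -> float:
    """``1 - concentric IoU``; the k-means metric. Dimensions must be positive."""
    a = np.atleast_1d(np.asarray(dim_a, dtype=float))
    b = np.atleast_1d(np.asarray(dim_b, dtype=float))
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("box dimensions must be positive")
    return 1.0 - concentric_iou(dim_a, dim_b, shape)


def _as_dims(gt_dims, shape: str) -> np.ndarray:
    d = np.asarray(gt_dims, dtype=float)
    if shape == "circle":
        d = d.reshape(-1)
        if d.ndim != 1:
            raise ValueError("circle dims must be 1-D radii")
    else:
        d = d.reshape(-1, 2)
    if np.any(d <= 0):
        raise ValueError("box dimensions must be positive")
    return d


def _sorted_anchor_set(centers: np.ndarray, shape: str) -> AnchorSet:
    areas = _areas(centers, shape)
    order = np.argsort(areas, kind="stable")
    centers = centers[order]
    k = len(centers)
    # three near-equal groups, smallest areas to the finest scale
    bounds = [round(k * i / 3) for i in range(4)]
    groups = tuple(tuple(range(bounds[i], bounds[i + 1])) for i in range(3))
    return AnchorSet(shape=shape, dims=centers, scale_assignment=groups)


def _kmeanspp_init(dims: np.ndarray, k: int, shape: str, rng: np.random.Generator) -> np.ndarray:
    n = len(dims)
    pts = dims if shape == "rect" else dims.reshape(-1, 1)
    chosen = [int(rng.integers(n))]
    d2 = None
    while len(chosen) < k:
        last = pts[chosen[-1]][None]
        dist = 1.0 - _concentric_iou_matrix(pts, last, shape)[:, 0]
        d2 = dist**2 if d2 is None else np.minimum(d2, dist**2)
        total = d2.sum()
        if total <= 0:
            chosen.append(int(rng.integers(n)))
            continue
        chosen.append(int(rng.choice(n, p=d2 / total)))
    return pts[chosen].copy()


def kmeans_anchors(
    gt_dims,
    k: int = 9,
    shape: str = "circle",
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> tuple[AnchorSet, float]:
    """Lloyd k-means under IoU distance; returns (AnchorSet, mean best IoU).

    Centroid update is the arithmetic mean of member dimensions.  Runs
    ``n_restarts`` k-means++ seedings and keeps the solution with the
    highest average best IoU.  Empty clusters are re-seeded from the point
    farthest from its centroid.  Deterministic given (seed, n_restarts).
    """
    dims = _as_dims(gt_dims, shape)
    n = len(dims)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of ground truths ({n})")
    pts = dims if shape == "rect" else dims.reshape(-1, 1)

    rng = np.random.default_rng(seed)
    best_centers, best_score = None, -1.0
    for _ in range(max(1, n_restarts)):
        centers = _kmeanspp_init(dims, k, shape, rng)
        assign = np.full(n, -1)
        for _ in range(max_iter):
            dist = 1.0 - _concentric_iou_matrix(pts, centers, shape)
            new_assign = dist.argmin(axis=1)
            for c in range(k):
                if not np.any(new_assign == c):
                    far = int(dist[np.arange(n), new_assign].argmax())
                    new_assign[far] = c
                    centers[c] = pts[far]
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for c in range(k):
                centers[c] = pts[assign == c].mean(axis=0)
        best_iou = _concentric_iou_matrix(pts, centers, shape).max(axis=1)
        score = float(best_iou.mean())
        if score > best_score:
            best_score, best_centers = score, centers.copy()

    flat = best_centers[:, 0] if shape == "circle" else best_centers
    return _sorted_anchor_set(flat, shape), best_score


def average_best_iou(gt_dims, anchors: AnchorSet) -> float:
    """Mean over ground truths of the best concentric IoU with any anchor."""
    dims = _as_dims(gt_dims, anchors.shape)
    if len(dims) == 0:
        raise ValueError("empty ground-truth list")
    pts = dims if anchors.shape == "rect" else dims.reshape(-1, 1)
    adims = anchors.dims if anchors.shape == "rect" else anchors.dims.reshape(-1, 1)
    return float(_concentric_iou_matrix(pts, adims, anchors.shape).max(axis=1).mean())
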
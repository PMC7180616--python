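"""Synthetic fruit-scene generation, detection perturbation, augmentation.

The generator emulates the structure of orchard/greenhouse fruit imagery at
the level a detection pipeline cares about: filled quasi-circular "fruit"
discs with radial shading on a cluttered background, partial occlusion by
elliptical "leaf" patches, fruit-fruit overlap, and two illumination
regimes (bright high-contrast "sunlight" vs dim low-contrast "shading").
Ground-truth circles are amodal — they describe the full fruit extent even
when part of it is hidden.

``perturb_detections`` closes the loop without a trained network: it
derives a noisy detection list from ground truth with planted miss rate,
false-positive rate and localization noise, so that evaluation code can be
tested against known true rates.

``augment`` implements the training-time augmentation policy: with equal
probability keep the original image or scale it by a Uniform[1.15, 1.25]
factor and crop a random patch of the original size; afterwards flip
horizontally with probability 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import CircleBox
from .nms import Detection

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "generate_scene",
    "perturb_detections",
    "augment",
]

logger = logging.getLogger(__name__)

SCALE_RANGE = (1.15, 1.25)
FLIP_PROB = 0.5


@dataclass(frozen=True)
class GroundTruth:
    """An annotated fruit: amodal circle, class, and condition tags."""

    box: CircleBox
    class_id: int = 0
    occlusion_tag: str = "slight"       # "slight" or "severe" (> 50% covered)
    illumination_tag: str = "sunlight"  # "sunlight" or "shading"


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Radii are log-normal (``radius_log_mu``/``radius_log_sigma`` on the log
    scale, in pixels); ``overlap_fraction`` is the probability a new fruit
    is deliberately placed overlapping an existing one;
    ``occluded_fraction`` of fruits receive a leaf occluder sized to cover
    about ``occlusion_severity`` of their area.  The illumination regime is
    drawn per scene with probability 1/2 each.
    """

    image_size: int = 256
    n_objects: tuple[int, int] = (4, 8)       # inclusive range
    radius_log_mu: float = math.log(18.0)
    radius_log_sigma: float = 0.25
    overlap_fraction: float = 0.3
    occluded_fraction: float = 0.5
    occlusion_severity: float = 0.6
    brightness_regimes: dict = field(
        default_factory=lambda: {"sunlight": (0.65, 0.30), "shading": (0.35, 0.12)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_fraction", "occluded_fraction", "occlusion_severity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.radius_log_sigma < 0:
            raise ValueError("radius_log_sigma must be non-negative")


def _disc_mask(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float, angle: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    ca, sa = math.cos(angle), math.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, list[GroundTruth]]:
    """Render one scene; returns (float image in [0, 1], ground truths).

    Fruits are drawn back to front, so a later fruit occludes an earlier
    one; leaf occluders are drawn last over the fruits selected for
    occlusion.  Each fruit's occlusion fraction is measured exactly from
    the rendered masks and sets its tag (severe when more than half the
    disc is covered).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    regime = "sunlight" if rng.random() < 0.5 else "shading"
    mean, contrast = spec.brightness_regimes[regime]

    # background clutter: smoothed noise around the regime mean
    bg = rng.normal(mean * 0.7, 1.0, (size, size))
    bg = ndimage.gaussian_filter(bg, sigma=4.0)
    sd = bg.std()
    img = mean * 0.7 + (bg - bg.mean()) * (0.08 / sd if sd > 0 else 0.0)

    lo, hi = spec.n_objects if isinstance(spec.n_objects, tuple) else (spec.n_objects, spec.n_objects)
    n_target = int(rng.integers(lo, hi + 1))

    circles: list[CircleBox] = []
    for _ in range(n_target):
        placed = False
        for _attempt in range(1000):
            r = float(np.exp(rng.normal(spec.radius_log_mu, spec.radius_log_sigma)))
            r = min(r, size / 5.0)
            want_overlap = len(circles) > 0 and rng.random() < spec.overlap_fraction
            if want_overlap:
                base = circles[int(rng.integers(len(circles)))]
                # moderate overlap: centers at 0.8-1.1 of the radius sum
                dist = (0.8 + 0.3 * rng.random()) * (base.r + r)
                ang = rng.uniform(0, 2 * math.pi)
                cx = base.cx + dist * math.cos(ang)
                cy = base.cy + dist * math.sin(ang)
            else:
                cx = rng.uniform(r, size - r)
                cy = rng.uniform(r, size - r)
            if not (r <= cx <= size - r and r <= cy <= size - r):
                continue
            cand = CircleBox(cx, cy, r)
            # keep pairwise overlap moderate so objects stay distinguishable
            too_close = any(
                math.hypot(c.cx - cx, c.cy - cy) < 0.75 * (c.r + r) for c in circles
            )
            if too_close:
                continue
            circles.append(cand)
            placed = True
            break
        if not placed:
            logger.warning("scene too crowded; placed %d of %d objects", len(circles), n_target)
            break

    # render fruits back to front with radial shading; track visibility
    owner = np.full((size, size), -1, dtype=int)
    yy, xx = np.mgrid[:size, :size]
    for i, c in enumerate(circles):
        mask = _disc_mask(size, c.cx, c.cy, c.r)
        rad = np.sqrt((xx - c.cx) ** 2 + (yy - c.cy) ** 2) / max(c.r, 1e-9)
        shade = mean + contrast * (0.9 - 0.7 * rad)
        img = np.where(mask, shade, img)
        owner[mask] = i

    # leaf occluders over a subset of fruits
    occluded = np.zeros((size, size), dtype=bool)
    for i, c in enumerate(circles):
        if rng.random() >= spec.occluded_fraction:
            continue
        # ellipse sized to cover ~occlusion_severity of the disc, offset to one side
        a = c.r * (0.8 + 0.8 * spec.occlusion_severity)
        b = c.r * (0.6 + 0.6 * spec.occlusion_severity)
        ang = rng.uniform(0, 2 * math.pi)
        off = c.r * (1.0 - spec.occlusion_severity)
        ecx = c.cx + off * math.cos(ang)
        ecy = c.cy + off * math.sin(ang)
        emask = _ellipse_mask(size, ecx, ecy, a, b, rng.uniform(0, math.pi))
        leaf_shade = mean * (0.55 + 0.1 * rng.random())
        img = np.where(emask, leaf_shade, img)
        occluded |= emask

    img = np.clip(img + rng.normal(0.0, 0.01, (size, size)), 0.0, 1.0)

    gts: list[GroundTruth] = []
    for i, c in enumerate(circles):
        mask = _disc_mask(size, c.cx, c.cy, c.r)
        total = int(mask.sum())
        visible = int(((owner == i) & ~occluded).sum())
        frac_covered = 1.0 - visible / total if total else 1.0
        gts.append(
            GroundTruth(
                box=c,
                occlusion_tag="severe" if frac_covered > 0.5 else "slight",
                illumination_tag=regime,
            )
        )
    return img, gts


def perturb_detections(
    gts,
    sigma_center: float = 1.5,
    sigma_logr: float = 0.05,
    miss_rate: float = 0.0,
    fp_rate: float = 0.0,
    image_size: int = 256,
    seed: int = 0,
) -> list[Detection]:
    """Derive a noisy detection list from ground truth with planted rates.

    Each ground truth is missed with probability ``miss_rate``; survivors
    are jittered with Gaussian center noise and log-normal radius noise and
    given a confidence that decreases with the jitter magnitude.  False
    positives are added as Poisson(``fp_rate`` * n_gt) random circles with
    low-skewed confidences.
    """
    for name, v in (("miss_rate", miss_rate), ("fp_rate", fp_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed)
    gts = list(gts)
    dets: list[Detection] = []
    for gt in gts:
        box = gt.box if hasattr(gt, "box") else gt
        if rng.random() < miss_rate:
            continue
        dx, dy = rng.normal(0.0, sigma_center, 2) if sigma_center > 0 else (0.0, 0.0)
        dlr = rng.normal(0.0, sigma_logr) if sigma_logr > 0 else 0.0
        jitter = (math.hypot(dx, dy) / max(box.r, 1e-9)) + abs(dlr)
        conf = float(np.clip(1.0 - 1.5 * jitter - 0.05 * rng.random(), 0.05, 1.0))
        if sigma_center == 0 and sigma_logr == 0:
            conf = 1.0
        dets.append(
            Detection(
                box=CircleBox(box.cx + dx, box.cy + dy, box.r * math.exp(dlr)),
                confidence=conf,
                class_probs=(1.0,),
            )
        )
    n_fp = int(rng.poisson(fp_rate * len(gts))) if fp_rate > 0 else 0
    for _ in range(n_fp):
        r = float(np.exp(rng.normal(math.log(15.0), 0.3)))
        cx = rng.uniform(r, max(image_size - r, r))
        cy = rng.uniform(r, max(image_size - r, r))
        conf = float(np.clip(rng.beta(2.0, 4.0), 0.05, 0.95))
        dets.append(Detection(box=CircleBox(cx, cy, r), confidence=conf, class_probs=(1.0,)))
    return dets


def augment(image: np.ndarray, gts, seed: int = 0) -> tuple[np.ndarray, list[GroundTruth]]:
    """Training-time augmentation of an image and its ground truths.

    With probability 1/2 the image is kept as is, otherwise scaled by a
    Uniform[1.15, 1.25] factor and a patch of the original size is cropped
    at a uniform random offset.  The result is then flipped horizontally
    with probability 1/2.  Ground-truth circles are transformed accordingly;
    a circle whose center leaves the crop is dropped.
    """
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    out = np.asarray(image, dtype=float)
    boxes = [(g.box if hasattr(g, "box") else g, g) for g in gts]

    do_scale = rng.random() < 0.5
    if do_scale:
        factor = rng.uniform(*SCALE_RANGE)
        zoomed = ndimage.zoom(out, factor, order=1)
        zh, zw = zoomed.shape[:2]
        oy = int(rng.integers(0, zh - h + 1))
        ox = int(rng.integers(0, zw - w + 1))
        out = zoomed[oy : oy + h, ox : ox + w]
        new_boxes = []
        for box, g in boxes:
            cx = box.cx * factor - ox
            cy = box.cy * factor - oy
            if 0 <= cx < w and 0 <= cy < h:
                new_boxes.append((CircleBox(cx, cy, box.r * factor), g))
        boxes = new_boxes

    do_flip = rng.random() < FLIP_PROB
    if do_flip:
        out = out[:, ::-1].copy()
        boxes = [(CircleBox(w - 1 - box.cx, box.cy, box.r), g) for box, g in boxes]

    new_gts = [
        GroundTruth(box=b, class_id=getattr(g, "class_id", 0),
                    occlusion_tag=getattr(g, "occlusion_tag", "slight"),
                    illumination_tag=getattr(g, "illumination_tag", "sunlight"))
        for b, g in boxes
    ]
    return out, new_gts
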
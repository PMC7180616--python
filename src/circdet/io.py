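"""Annotation and detection file formats.

One CSV dialect for both circles and rectangles, with header
``image_id,shape,cx,cy,r,w,h,class,conf,tags``: circles fill ``r`` and
leave ``w,h`` empty, rectangles the opposite; ``conf`` is empty for ground
truth; ``tags`` is a semicolon-joined ``key=value`` list.  A JSON-lines
dialect carries the same fields.  Pascal-VOC XML can be imported (rects
only): ``xmin/ymin/xmax/ymax`` are converted to center format under a
0-based, half-open pixel convention (xmax/ymax exclusive).

All coordinates are continuous pixels, origin top-left, y down; floats are
written with six decimal places, records sorted by (image_id, confidence
descending) for stable output.
"""

from __future__ import annotations

import csv
import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .geometry import CircleBox, RectBox
from .nms import Detection
from .synthetic import GroundTruth

__all__ = [
    "AnnotationRecord",
    "read_annotations",
    "write_annotations",
    "read_voc_xml",
    "records_to_detections",
    "records_to_ground_truths",
    "detections_to_records",
    "ground_truths_to_records",
]

CSV_HEADER = ["image_id", "shape", "cx", "cy", "r", "w", "h", "class", "conf", "tags"]


@dataclass(frozen=True)
class AnnotationRecord:
    image_id: str
    shape: str                      # "circle" or "rect"
    coords: tuple[float, ...]       # (cx, cy, r) or (cx, cy, w, h)
    class_id: int = 0
    confidence: float | None = None # None for ground truth
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "rect"):
            raise ValueError(f"unknown shape {self.shape!r}")
        want = 3 if self.shape == "circle" else 4
        if len(self.coords) != want:
            raise ValueError(f"{self.shape} record needs {want} coords, got {len(self.coords)}")
        if any(not math.isfinite(c) for c in self.coords):
            raise ValueError("coordinates must be finite")
        if any(c < 0 for c in self.coords[2:]):
            raise ValueError("sizes must be non-negative")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def box(self) -> CircleBox | RectBox:
        if self.shape == "circle":
            return CircleBox(*self.coords)
        return RectBox(*self.coords)


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _parse_tags(s: str) -> dict:
    if not s:
        return {}
    out = {}
    for item in s.split(";"):
        k, _, v = item.partition("=")
        out[k] = v
    return out


def _row_to_record(row: dict, lineno: int) -> AnnotationRecord:
    try:
        shape = row["shape"]
        cx, cy = float(row["cx"]), float(row["cy"])
        if shape == "circle":
            coords = (cx, cy, float(row["r"]))
        elif shape == "rect":
            coords = (cx, cy, float(row["w"]), float(row["h"]))
        else:
            raise ValueError(f"unknown shape {shape!r}")
        conf = row.get("conf") or None
        return AnnotationRecord(
            image_id=row["image_id"],
            shape=shape,
            coords=coords,
            class_id=int(row.get("class") or 0),
            confidence=float(conf) if conf is not None else None,
            tags=_parse_tags(row.get("tags") or ""),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed annotation at line {lineno}: {exc}") from exc


def read_annotations(path, dialect: str = "csv") -> list[AnnotationRecord]:
    """Read annotation records from CSV or JSON-lines."""
    path = Path(path)
    records: list[AnnotationRecord] = []
    if dialect == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                records.append(_row_to_record(row, lineno))
    elif dialect == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                obj.setdefault("tags", "")
                if isinstance(obj.get("tags"), dict):
                    obj["tags"] = ";".join(f"{k}={v}" for k, v in obj["tags"].items())
                records.append(_row_to_record(obj, lineno))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return records


def write_annotations(records, path, dialect: str = "csv") -> None:
    """Write records with deterministic formatting and ordering."""
    path = Path(path)
    recs = sorted(
        records,
        key=lambda r: (r.image_id, -(r.confidence if r.confidence is not None else 2.0)),
    )
    rows = []
    for r in recs:
        row = {
            "image_id": r.image_id,
            "shape": r.shape,
            "cx": _fmt(r.coords[0]),
            "cy": _fmt(r.coords[1]),
            "r": _fmt(r.coords[2]) if r.shape == "circle" else "",
            "w": _fmt(r.coords[2]) if r.shape == "rect" else "",
            "h": _fmt(r.coords[3]) if r.shape == "rect" else "",
            "class": str(r.class_id),
            "conf": _fmt(r.confidence) if r.confidence is not None else "",
            "tags": ";".join(f"{k}={v}" for k, v in sorted(r.tags.items())),
        }
        rows.append(row)
    if dialect == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_HEADER)
            writer.writeheader()
            writer.writerows(rows)
    elif dialect == "jsonl":
        with path.open("w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_voc_xml(path) -> list[AnnotationRecord]:
    """Import Pascal-VOC XML object annotations as rectangle records.

    xmin/ymin/xmax/ymax are treated as 0-based half-open pixel bounds, so
    a box (0, 0, 4, 4) becomes center (2, 2) with w = h = 4.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    image_id = (root.findtext("filename") or path.stem).rsplit(".", 1)[0]
    records = []
    for obj in root.iter("object"):
        bb = obj.find("bndbox")
        if bb is None:
            continue
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        w, h = xmax - xmin, ymax - ymin
        records.append(
            AnnotationRecord(
                image_id=image_id,
                shape="rect",
                coords=((xmin + xmax) / 2.0, (ymin + ymax) / 2.0, w, h),
                class_id=0,
                tags={"name": obj.findtext("name") or ""},
            )
        )
    return records


def records_to_detections(records) -> list[Detection]:
    return [
        Detection(box=r.box, confidence=r.confidence if r.confidence is not None else 1.0)
        for r in records
    ]


def records_to_ground_truths(records) -> list[GroundTruth]:
    out = []
    for r in records:
        if r.shape != "circle":
            raise ValueError("ground-truth conversion expects circle records")
        out.append(
            GroundTruth(
                box=r.box,
                class_id=r.class_id,
                occlusion_tag=r.tags.get("occlusion", "slight"),
                illumination_tag=r.tags.get("illumination", "sunlight"),
            )
        )
    return out


def detections_to_records(dets, image_id: str = "image") -> list[AnnotationRecord]:
    out = []
    for d in dets:
        if isinstance(d.box, CircleBox):
            rec = AnnotationRecord(image_id, "circle", (d.box.cx, d.box.cy, d.box.r),
                                   d.class_id, d.confidence)
        else:
            rec = AnnotationRecord(image_id, "rect", (d.box.cx, d.box.cy, d.box.w, d.box.h),
                                   d.class_id, d.confidence)
        out.append(rec)
    return out


def ground_truths_to_records(gts, image_id: str = "image") -> list[AnnotationRecord]:
    return [
        AnnotationRecord(
            image_id, "circle", (g.box.cx, g.box.cy, g.box.r), g.class_id,
            tags={"occlusion": g.occlusion_tag, "illumination": g.illumination_tag},
        )
        for g in gts
    ]
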
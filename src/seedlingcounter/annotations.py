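"""Annotation dialects: LabelMe JSON in, COCO detection JSON out.

Boxes are stored internally as (x_min, y_min, x_max, y_max); COCO bboxes are
(x, y, width, height). The category table always contains the single class
``seedling``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

CATEGORY = {"id": 1, "name": "seedling", "supercategory": "plant"}


class AnnotationError(ValueError):
    """Raised with an itemized report of malformed annotation entries."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def _shape_to_box(shape: dict, index: int, problems: list[str]):
    points = shape.get("points")
    stype = shape.get("shape_type", "polygon")
    if not points or not isinstance(points, list):
        problems.append(f"shape {index}: missing points")
        return None
    try:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    except Exception:
        problems.append(f"shape {index}: malformed points")
        return None
    if stype == "rectangle":
        if len(pts) != 2:
            problems.append(f"shape {index}: rectangle needs exactly 2 points")
            return None
    elif stype == "polygon":
        if len(pts) < 3:
            problems.append(f"shape {index}: polygon needs at least 3 points")
            return None
    else:
        problems.append(f"shape {index}: unsupported shape_type {stype!r}")
        return None
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 <= x0 or y1 <= y0:
        problems.append(f"shape {index}: degenerate extent")
        return None
    return float(x0), float(y0), float(x1), float(y1)


def labelme_to_coco(documents: list[dict] | dict,
                    image_names: list[str] | None = None) -> dict:
    """Convert LabelMe documents (rectangles / polygons) to COCO ground truth.

    Polygons become their tight bounding boxes. Annotation ids are
    consecutive from 1 across all documents.
    """
    if isinstance(documents, dict):
        documents = [documents]
    images, annotations, problems = [], [], []
    ann_id = 1
    for img_id, doc in enumerate(documents, start=1):
        if not isinstance(doc, dict) or "shapes" not in doc:
            problems.append(f"document {img_id}: not a LabelMe document")
            continue
        name = (image_names[img_id - 1] if image_names
                else doc.get("imagePath", f"image_{img_id}.png"))
        images.append({
            "id": img_id,
            "file_name": name,
            "width": int(doc.get("imageWidth", 0)),
            "height": int(doc.get("imageHeight", 0)),
        })
        for i, shape in enumerate(doc["shapes"]):
            box = _shape_to_box(shape, i, problems)
            if box is None:
                continue
            x0, y0, x1, y1 = box
            annotations.append({
                "id": ann_id,
                "image_id": img_id,
                "category_id": CATEGORY["id"],
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0),
                "iscrowd": 0,
            })
            ann_id += 1
    if problems:
        raise AnnotationError(problems)
    return {"images": images, "annotations": annotations, "categories": [CATEGORY]}


def boxes_to_coco(boxes_by_image: dict[str, np.ndarray],
                  image_sizes: dict[str, tuple[int, int]] | None = None) -> dict:
    """Build COCO ground truth from per-image (x0, y0, x1, y1) box arrays."""
    images, annotations = [], []
    ann_id = 1
    for img_id, (name, boxes) in enumerate(boxes_by_image.items(), start=1):
        w, h = (image_sizes or {}).get(name, (0, 0))
        images.append({"id": img_id, "file_name": name, "width": w, "height": h})
        for x0, y0, x1, y1 in np.asarray(boxes, dtype=np.float64).reshape(-1, 4):
            annotations.append({
                "id": ann_id, "image_id": img_id, "category_id": CATEGORY["id"],
                "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                "area": float((x1 - x0) * (y1 - y0)), "iscrowd": 0,
            })
            ann_id += 1
    return {"images": images, "annotations": annotations, "categories": [CATEGORY]}


def coco_to_boxes(coco: dict) -> dict[str, np.ndarray]:
    """Inverse of :func:`boxes_to_coco` (lossless for boxes)."""
    name_by_id = {img["id"]: img["file_name"] for img in coco["images"]}
    out: dict[str, list] = {name: [] for name in name_by_id.values()}
    for ann in coco["annotations"]:
        x, y, w, h = ann["bbox"]
        out[name_by_id[ann["image_id"]]].append([x, y, x + w, y + h])
    return {name: np.asarray(b, dtype=np.float64).reshape(-1, 4)
            for name, b in out.items()}


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1))
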
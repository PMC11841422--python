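"""Axis-aligned box utilities.

Boxes are ``(x_min, y_min, x_max, y_max)`` in pixels, 0-based, half-open:
a box covers columns ``x_min <= x < x_max``. Areas are therefore
``(x_max - x_min) * (y_max - y_min)``.
"""

from __future__ import annotations

import numpy as np


class DetectionSet:
    """Scored single-class boxes for one image, kept sorted by score."""

    def __init__(self, boxes=None, scores=None):
        boxes = np.zeros((0, 4)) if boxes is None else np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
        scores = np.zeros(0) if scores is None else np.asarray(scores, dtype=np.float64).ravel()
        if len(boxes) != len(scores):
            raise ValueError("boxes and scores disagree in length")
        if len(scores) and ((scores < 0).any() or (scores > 1).any()):
            raise ValueError("scores must lie in [0, 1]")
        boxes = validate_boxes(boxes)
        order = np.argsort(-scores, kind="stable")
        self.boxes = boxes[order]
        self.scores = scores[order]

    def __len__(self) -> int:
        return len(self.scores)

    def above(self, threshold: float) -> "DetectionSet":
        keep = self.scores > threshold
        return DetectionSet(self.boxes[keep], self.scores[keep])

    def to_coco_results(self, image_id: int, category_id: int = 1) -> list[dict]:
        out = []
        for (x0, y0, x1, y1), s in zip(self.boxes, self.scores):
            out.append({"image_id": image_id, "category_id": category_id,
                        "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                        "score": float(s)})
        return out


def validate_boxes(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    if boxes.size and not np.isfinite(boxes).all():
        raise ValueError("boxes contain non-finite coordinates")
    if boxes.size and not ((boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])).all():
        raise ValueError("boxes must satisfy x_max > x_min and y_max > y_min")
    return boxes


def box_areas(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    return (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union; shape (len(a), len(b))."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    union = box_areas(a)[:, None] + box_areas(b)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def clip_boxes(boxes: np.ndarray, width: float, height: float) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4).copy()
    boxes[:, 0] = np.clip(boxes[:, 0], 0, width)
    boxes[:, 2] = np.clip(boxes[:, 2], 0, width)
    boxes[:, 1] = np.clip(boxes[:, 1], 0, height)
    boxes[:, 3] = np.clip(boxes[:, 3], 0, height)
    return boxes
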
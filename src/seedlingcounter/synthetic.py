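"""Seeded synthetic UAV field scenes with controllable object statistics.

Scenes imitate the statistics that matter to the detection stack — tile
size, ground-sampling distance, row structure, and the small/medium object
area mix — not photorealism. Soil is low-frequency correlated brown noise;
each seedling is a rosette of elongated green lobes whose tight bounding
box hits a requested area class (area <= 32^2 px small, otherwise medium).

All operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .annotations import boxes_to_coco, labelme_to_coco  # noqa: F401  (re-export)
from .boxes import box_areas
from .metrics import SMALL_MAX_AREA, size_class

logger = logging.getLogger(__name__)

SOIL_BASE = np.array([132.0, 101.0, 68.0])
PLANT_BASE = np.array([52.0, 148.0, 46.0])

#: ground-sampling distances (cm/px) of the 12 / 20 / 24 m flights
STANDARD_GSD = (0.32, 0.54, 0.64)


@dataclass(frozen=True)
class FieldConfig:
    image_size: int = 512
    gsd_cm_per_px: float = 0.32
    n_rows: int = 4
    plants_per_row: int = 8
    position_jitter: float = 0.15   # fraction of the row/plant spacing
    small_fraction: float = 0.89
    min_box_side: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64")
        if not 0 <= self.small_fraction <= 1:
            raise ValueError("small_fraction must lie in [0, 1]")
        if self.gsd_cm_per_px <= 0:
            raise ValueError("gsd must be positive")


@dataclass
class SyntheticScene:
    image: np.ndarray                       # (H, W, 3) uint8
    boxes: np.ndarray                       # (N, 4) float, tight, half-open
    size_labels: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def __post_init__(self):
        b = self.boxes
        if len(b) and not ((b[:, 0] >= 0).all() and (b[:, 1] >= 0).all()
                           and (b[:, 2] <= self.width).all() and (b[:, 3] <= self.height).all()):
            raise ValueError("boxes must lie within the image")


def _soil_background(size_hw: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = size_hw
    coarse = rng.normal(0, 1, (max(h // 16, 2), max(w // 16, 2), 3))
    smooth = np.stack([ndimage.zoom(coarse[..., c], (h / coarse.shape[0], w / coarse.shape[1]), order=1)
                       for c in range(3)], axis=-1)
    fine = rng.normal(0, 4, (h, w, 3))
    img = SOIL_BASE + 14 * smooth[:h, :w] + fine
    return np.clip(img, 0, 255)


def _lobe_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Rosette of 3-6 elongated lobes, resampled to exactly (h, w) tight."""
    res = 4 * max(h, w, 8)
    yy, xx = np.mgrid[0:res, 0:res]
    cy = cx = (res - 1) / 2.0
    mask = np.zeros((res, res), bool)
    for _ in range(rng.integers(3, 7)):
        theta = rng.uniform(0, 2 * np.pi)
        length = res / 2.0 * rng.uniform(0.7, 1.0)
        width = max(length * rng.uniform(0.22, 0.38), 1.5)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= ((u - length / 2) ** 2 / (length / 2) ** 2 + v**2 / width**2) <= 1.0
    ys, xs = np.nonzero(mask)
    mask = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    mh, mw = mask.shape
    rows = np.round(np.linspace(0, mh - 1, h)).astype(int)
    cols = np.round(np.linspace(0, mw - 1, w)).astype(int)
    out = mask[np.ix_(rows, cols)]
    # guarantee tightness after resampling
    for edge in (out[0], out[-1], out[:, 0], out[:, -1]):
        if not edge.any():
            edge[len(edge) // 2] = True
    return out


def _sample_box_dims(cls: str, max_side: int, min_side: int,
                     rng: np.random.Generator) -> tuple[int, int]:
    """Box dimensions whose product lands in the requested area class.

    Areas are drawn log-uniform inside the class range so boundary cases
    occur; dimensions are nudged after rounding if rounding crossed the
    class boundary.
    """
    if cls == "small":
        lo, hi = float(min_side**2), float(SMALL_MAX_AREA)
    else:
        lo, hi = float(SMALL_MAX_AREA + 1), float(min(96 * 96, max_side**2))
    hi = max(hi, lo + 1)
    for _ in range(50):
        area = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        aspect = rng.uniform(0.7, 1.4)
        w = int(np.clip(round(np.sqrt(area * aspect)), min_side, max_side))
        h = int(np.clip(round(area / w), min_side, max_side))
        if size_class(w * h) == cls:
            return w, h
    # fall back to a guaranteed member of the class
    side = 16 if cls == "small" else 40
    return side, side


def generate_scene(cfg: FieldConfig) -> SyntheticScene:
    """Render one field tile with row-structured seedlings.

    Placement failures (overcrowding) reduce the object count with a logged
    warning instead of failing.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    image = _soil_background((size, size), rng)

    row_gap = size / cfg.n_rows
    col_gap = size / cfg.plants_per_row
    max_side = max(cfg.min_box_side + 1, min(96, size // 3))

    boxes: list[list[float]] = []
    labels: list[str] = []
    failures = 0
    for i in range(cfg.n_rows):
        for j in range(cfg.plants_per_row):
            cls = "small" if rng.random() < cfg.small_fraction else "medium"
            w, h = _sample_box_dims(cls, max_side, cfg.min_box_side, rng)
            placed = False
            for _ in range(4):
                cy = (i + 0.5) * row_gap + rng.normal(0, cfg.position_jitter * row_gap)
                cx = (j + 0.5) * col_gap + rng.normal(0, cfg.position_jitter * col_gap)
                x0 = int(np.clip(round(cx - w / 2), 0, size - w))
                y0 = int(np.clip(round(cy - h / 2), 0, size - h))
                candidate = np.array([x0, y0, x0 + w, y0 + h], dtype=np.float64)
                if boxes:
                    existing = np.asarray(boxes)
                    ix = np.minimum(existing[:, 2], candidate[2]) - np.maximum(existing[:, 0], candidate[0])
                    iy = np.minimum(existing[:, 3], candidate[3]) - np.maximum(existing[:, 1], candidate[1])
                    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
                    if (inter > 0.25 * min(w * h, box_areas(existing).min())).any():
                        continue
                mask = _lobe_mask(h, w, rng)
                region = image[y0:y0 + h, x0:x0 + w]
                color = PLANT_BASE + rng.normal(0, 10, 3)
                region[mask] = np.clip(color + rng.normal(0, 6, (int(mask.sum()), 3)), 0, 255)
                boxes.append(list(candidate))
                labels.append(size_class(w * h))
                placed = True
                break
            if not placed:
                failures += 1
    if failures:
        logger.warning("placement failed for %d of %d objects (overcrowding)",
                       failures, cfg.n_rows * cfg.plants_per_row)
    return SyntheticScene(
        image=image.astype(np.uint8),
        boxes=np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
        size_labels=labels,
        provenance={"config": cfg.__dict__ | {}, "seed": cfg.seed,
                    "placement_failures": failures},
    )


def generate_dataset(n_scenes: int, cfg: FieldConfig) -> list[SyntheticScene]:
    """Scenes seeded ``cfg.seed, cfg.seed+1, ...`` for reproducibility."""
    return [generate_scene(replace(cfg, seed=cfg.seed + k)) for k in range(n_scenes)]


def altitude_rescale(scene: SyntheticScene, gsd_from: float, gsd_to: float) -> SyntheticScene:
    """Re-render a scene as if captured at a different ground-sampling
    distance: a 0.32 -> 0.64 cm/px rescale halves linear object size.

    Objects shrunk below 2 px on a side are dropped with a warning.
    """
    if gsd_from <= 0 or gsd_to <= 0:
        raise ValueError("gsd values must be positive")
    if gsd_from == gsd_to:
        return SyntheticScene(scene.image.copy(), scene.boxes.copy(),
                              list(scene.size_labels), dict(scene.provenance))
    factor = gsd_from / gsd_to
    new_h = max(2, round(scene.height * factor))
    new_w = max(2, round(scene.width * factor))
    img = np.stack([ndimage.zoom(scene.image[..., c].astype(np.float64),
                                 (new_h / scene.height, new_w / scene.width), order=1)
                    for c in range(3)], axis=-1)
    boxes = scene.boxes * factor
    keep = (boxes[:, 2] - boxes[:, 0] >= 2) & (boxes[:, 3] - boxes[:, 1] >= 2)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} objects below 2 px after rescaling")
    boxes = np.clip(boxes[keep], 0, [new_w, new_h, new_w, new_h])
    labels = [size_class(a) for a in box_areas(boxes)]
    prov = dict(scene.provenance) | {"gsd_rescale": (gsd_from, gsd_to)}
    return SyntheticScene(np.clip(img, 0, 255).astype(np.uint8), boxes, labels, prov)


@dataclass(frozen=True)
class AugmentConfig:
    flip_prob: float = 0.5
    scales: tuple[float, ...] = (0.8, 0.9, 1.0, 1.1, 1.2)
    crop_fraction: float = 0.8
    output_size: int | None = None  # None -> keep input size


def _flip_boxes_h(boxes: np.ndarray, width: float) -> np.ndarray:
    out = boxes.copy()
    out[:, 0] = width - boxes[:, 2]
    out[:, 2] = width - boxes[:, 0]
    return out


def _flip_boxes_v(boxes: np.ndarray, height: float) -> np.ndarray:
    out = boxes.copy()
    out[:, 1] = height - boxes[:, 3]
    out[:, 3] = height - boxes[:, 1]
    return out


def _resize_scene(image: np.ndarray, boxes: np.ndarray,
                  new_h: int, new_w: int) -> tuple[np.ndarray, np.ndarray]:
    h, w = image.shape[:2]
    if (new_h, new_w) == (h, w):
        return image, boxes
    img = np.stack([ndimage.zoom(image[..., c].astype(np.float64),
                                 (new_h / h, new_w / w), order=1)
                    for c in range(3)], axis=-1)
    scaled = boxes * np.array([new_w / w, new_h / h, new_w / w, new_h / h])
    return np.clip(img, 0, 255).astype(np.uint8), scaled


def _has_plant_pixels(image: np.ndarray, box: np.ndarray) -> bool:
    x0, y0, x1, y1 = (int(np.floor(box[0])), int(np.floor(box[1])),
                      int(np.ceil(box[2])), int(np.ceil(box[3])))
    patch = image[max(y0, 0):y1, max(x0, 0):x1]
    if patch.size == 0:
        return False
    return bool((patch[..., 1].astype(int) > patch[..., 0].astype(int) + 10).any())


def augment_scene(scene: SyntheticScene, aug: AugmentConfig = AugmentConfig(),
                  seed: int = 0, decisions: dict | None = None) -> SyntheticScene:
    """Flip -> random resize -> random crop -> resize to fixed size.

    ``decisions`` forces the stochastic choices (keys ``flip_h``, ``flip_v``,
    ``scale``, ``crop_origin``) for reproducible tests. Boxes left without
    any rendered plant pixels after cropping are removed; an empty scene is
    a legal outcome.
    """
    rng = np.random.default_rng(seed)
    decisions = decisions or {}
    image, boxes = scene.image, scene.boxes.copy()

    flip_h = decisions.get("flip_h", rng.random() < aug.flip_prob)
    flip_v = decisions.get("flip_v", rng.random() < aug.flip_prob)
    if flip_h:
        image = image[:, ::-1]
        boxes = _flip_boxes_h(boxes, scene.width)
    if flip_v:
        image = image[::-1]
        boxes = _flip_boxes_v(boxes, scene.height)

    scale = decisions.get("scale", aug.scales[rng.integers(len(aug.scales))])
    image, boxes = _resize_scene(image, boxes,
                                 max(2, round(image.shape[0] * scale)),
                                 max(2, round(image.shape[1] * scale)))

    h, w = image.shape[:2]
    ch, cw = max(2, round(h * aug.crop_fraction)), max(2, round(w * aug.crop_fraction))
    oy, ox = decisions.get("crop_origin",
                           (int(rng.integers(h - ch + 1)), int(rng.integers(w - cw + 1))))
    image = np.ascontiguousarray(image[oy:oy + ch, ox:ox + cw])
    boxes = boxes - np.array([ox, oy, ox, oy], dtype=np.float64)
    boxes = np.clip(boxes, 0, [cw, ch, cw, ch])
    keep = (boxes[:, 2] - boxes[:, 0] > 1) & (boxes[:, 3] - boxes[:, 1] > 1)
    boxes = boxes[keep]
    keep2 = np.array([_has_plant_pixels(image, b) for b in boxes], bool) if len(boxes) else np.zeros(0, bool)
    boxes = boxes[keep2]

    out_size = aug.output_size or scene.image.shape[0]
    image, boxes = _resize_scene(image, boxes, out_size, out_size)
    labels = [size_class(a) for a in box_areas(boxes)] if len(boxes) else []
    prov = dict(scene.provenance) | {
        "augment": {"flip_h": bool(flip_h), "flip_v": bool(flip_v),
                    "scale": float(scale), "crop_origin": (oy, ox), "seed": seed}}
    return SyntheticScene(image, boxes, labels, prov)


def split_dataset(scenes: list, ratios: tuple[int, int, int] = (7, 2, 1),
                  seed: int = 0) -> tuple[list, list, list]:
    """Seeded shuffle, floor allocation, remainder to the training split."""
    n = len(scenes)
    if n < sum(ratios):
        raise ValueError(f"need at least {sum(ratios)} scenes to split {ratios}")
    total = sum(ratios)
    n_train = n * ratios[0] // total
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    n_train += n - (n_train + n_val + n_test)  # remainder to train
    order = np.random.default_rng(seed).permutation(n)
    train = [scenes[i] for i in order[:n_train]]
    val = [scenes[i] for i in order[n_train:n_train + n_val]]
    test = [scenes[i] for i in order[n_train + n_val:]]
    return train, val, test


def split_sizes(n: int, ratios: tuple[int, int, int] = (7, 2, 1)) -> tuple[int, int, int]:
    """The floor+remainder-to-train allocation rule, in closed form."""
    total = sum(ratios)
    base = [n * r // total for r in ratios]
    base[0] += n - sum(base)
    return tuple(base)


def scenes_to_coco(scenes: list[SyntheticScene],
                   names: list[str] | None = None) -> dict:
    names = names or [f"scene_{i:04d}.png" for i in range(len(scenes))]
    coco = boxes_to_coco({name: s.boxes for name, s in zip(names, scenes)},
                         {name: (s.width, s.height) for name, s in zip(names, scenes)})
    return coco
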
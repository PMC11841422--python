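"""Compact single-class reference detector.

Hosts the self-calibrated backbone and the fusion neck so the three ablation
axes (pretrained warm-up, RSCconv, ASCFF) can be exercised end-to-end on a
CPU. The head is a center-heatmap head (objectness peak + box size + center
offset at stride 4) rather than a transformer decoder: it is single-class,
anchor-free and cheap, and the components under test live in the backbone
and neck. "Pretrained" at desk scale means a brief autoencoding warm-up of
the backbone on the training scenes standing in for ImageNet weights.

The network is fully convolutional, so inference runs on any image size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .ascff import AscffNeck, ChannelMapperNeck
from .boxes import DetectionSet, clip_boxes
from .nn import AdamW, Conv2d, LayerNorm2d, Module, Tensor
from .nn import functional as F
from .rscconv import patch_backbone
from .synthetic import SyntheticScene

HEAD_STRIDE = 4


@dataclass(frozen=True)
class DetectorConfig:
    width: int = 4                      # base backbone channel width
    neck_channels: int = 16
    image_size: int = 64
    use_pretrained: bool = False
    use_rscconv: bool = False
    use_ascff: bool = False
    gate_calibration: bool = True
    attention_reduction: int = 4
    attention_spatial_kernel: int = 7
    learning_rate: float = 0.002
    weight_decay: float = 0.0001
    epochs: int = 12
    batch_size: int = 8
    backbone_lr_multiplier: float = 0.1
    pretrain_epochs: int = 4
    grad_clip_norm: float = 5.0  # multiplicative fusion can spike gradients
    val_every: int = 1           # epochs between validation AP evaluations
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if not 0 < self.backbone_lr_multiplier <= 1:
            raise ValueError("backbone_lr_multiplier must lie in (0, 1]")


class ResidualBlock(Module):
    """Bottleneck-style block with exactly one (patchable) 3x3 convolution."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(in_channels, out_channels, 1, rng=rng)
        self.conv3 = Conv2d(out_channels, out_channels, 3, stride=stride, padding=1, rng=rng)
        self.conv2 = Conv2d(out_channels, out_channels, 1, rng=rng)
        self.norm1 = LayerNorm2d(out_channels)
        self.norm3 = LayerNorm2d(out_channels)
        self.norm2 = LayerNorm2d(out_channels)
        self.skip = (None if stride == 1 and in_channels == out_channels
                     else Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm3(self.conv3(y)).relu()
        y = self.norm2(self.conv2(y))
        s = x if self.skip is None else self.skip(x)
        return (y + s).relu()


class Backbone(Module):
    """Stem + four residual stages; the last three feed the neck
    (strides 8 / 16 / 32, channels 2w / 4w / 8w)."""

    def __init__(self, width: int = 4, rng: np.random.Generator | None = None):
        w = width
        self.stem = Conv2d(3, w, 3, stride=2, padding=1, rng=rng)
        self.stem_norm = LayerNorm2d(w)
        self.stages = [
            ResidualBlock(w, w, stride=2, rng=rng),
            ResidualBlock(w, 2 * w, stride=2, rng=rng),
            ResidualBlock(2 * w, 4 * w, stride=2, rng=rng),
            ResidualBlock(4 * w, 8 * w, stride=2, rng=rng),
        ]
        self.width = width

    @property
    def out_channels(self) -> tuple[int, int, int]:
        w = self.width
        return (2 * w, 4 * w, 8 * w)

    def residual_blocks(self):
        for i, block in enumerate(self.stages):
            yield f"stages.{i}", block

    def forward(self, x: Tensor) -> list[Tensor]:
        x = self.stem_norm(self.stem(x)).relu()
        feats = []
        for block in self.stages:
            x = block(x)
            feats.append(x)
        return feats[1:]  # strides 8, 16, 32


class Head(Module):
    """Center-heatmap head at stride 4: 1 objectness + 2 log-size + 2 offset
    channels, decoded from the finest neck output upsampled 2x."""

    def __init__(self, in_channels: int, rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(in_channels, in_channels, 3, padding=1, rng=rng)
        self.norm1 = LayerNorm2d(in_channels)
        self.out = Conv2d(in_channels, 5, 3, padding=1, rng=rng)
        # bias the objectness logit low so early training sees few peaks
        self.out.bias.data[0] = -2.0

    def forward(self, finest: Tensor) -> Tensor:
        n, c, h, w = finest.shape
        up = F.bilinear_resize(finest, 2 * h, 2 * w)
        return self.out(self.norm1(self.conv1(up)).relu())


class DetectorModel(Module):
    def __init__(self, cfg: DetectorConfig,
                 pretrained_state: dict[str, np.ndarray] | None = None):
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg.width, rng=rng)
        if pretrained_state is not None:
            self.backbone.load_state_dict(pretrained_state)
        if cfg.use_rscconv:
            _, self.patch_report = patch_backbone(
                self.backbone, True, gate_calibration=cfg.gate_calibration)
        else:
            self.patch_report = []
        if cfg.use_ascff:
            self.neck = AscffNeck(self.backbone.out_channels, cfg.neck_channels,
                                  reduction=cfg.attention_reduction,
                                  spatial_kernel=cfg.attention_spatial_kernel, rng=rng)
        else:
            self.neck = ChannelMapperNeck(self.backbone.out_channels,
                                          cfg.neck_channels, rng=rng)
        self.head = Head(cfg.neck_channels, rng=rng)
        self.cfg = cfg

    def forward(self, images: Tensor) -> Tensor:
        pyramid = self.backbone(images)
        neck_out = self.neck(pyramid)
        return self.head(neck_out[0])


def build_model(cfg: DetectorConfig,
                pretrained_state: dict[str, np.ndarray] | None = None) -> DetectorModel:
    """Assemble a detector; initialization is a pure function of cfg.seed."""
    return DetectorModel(cfg, pretrained_state)


# -- input handling -----------------------------------------------------------

def _to_input(image: np.ndarray) -> np.ndarray:
    """HWC uint8/float image -> normalized 1x3xHxW float."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if not np.isfinite(np.asarray(arr, dtype=np.float64)).all():
        raise ValueError("non-finite pixel values")
    x = arr.astype(np.float64) / 255.0 - 0.5
    return x.transpose(2, 0, 1)[None]


# -- training targets and loss ------------------------------------------------

def _make_targets(boxes: np.ndarray, grid_h: int, grid_w: int) -> tuple[np.ndarray, ...]:
    heat = np.zeros((grid_h, grid_w))
    size_t = np.zeros((2, grid_h, grid_w))
    off_t = np.zeros((2, grid_h, grid_w))
    pos = np.zeros((grid_h, grid_w), bool)
    for x0, y0, x1, y1 in boxes:
        w, h = x1 - x0, y1 - y0
        cx, cy = (x0 + x1) / 2 / HEAD_STRIDE, (y0 + y1) / 2 / HEAD_STRIDE
        j, i = int(cx), int(cy)
        if not (0 <= i < grid_h and 0 <= j < grid_w):
            continue
        radius = max(1, int(round(min(w, h) / (2 * HEAD_STRIDE))))
        sigma = (2 * radius + 1) / 6.0
        ii, jj = np.mgrid[max(0, i - 2 * radius):min(grid_h, i + 2 * radius + 1),
                          max(0, j - 2 * radius):min(grid_w, j + 2 * radius + 1)]
        g = np.exp(-((ii - i) ** 2 + (jj - j) ** 2) / (2 * sigma**2))
        heat[ii, jj] = np.maximum(heat[ii, jj], g)
        heat[i, j] = 1.0
        pos[i, j] = True
        size_t[:, i, j] = np.log(max(w, 1.0) / HEAD_STRIDE), np.log(max(h, 1.0) / HEAD_STRIDE)
        off_t[:, i, j] = cx - j, cy - i
    return heat, size_t, off_t, pos


def detection_loss(pred: Tensor, boxes_batch: list[np.ndarray]) -> Tensor:
    """Penalty-reduced focal loss on the heatmap + L1 on size/offset."""
    n, _, gh, gw = pred.shape
    heats, sizes, offs, poss = [], [], [], []
    for boxes in boxes_batch:
        h, s, o, p = _make_targets(boxes, gh, gw)
        heats.append(h); sizes.append(s); offs.append(o); poss.append(p)
    heat_t = np.stack(heats)[:, None]
    size_t = np.stack(sizes)
    off_t = np.stack(offs)
    pos = np.stack(poss)[:, None]
    n_pos = max(int(pos.sum()), 1)

    p = pred[:, 0:1].sigmoid().clip(1e-6, 1 - 1e-6)
    pos_f = pos.astype(np.float64)
    neg_w = (1.0 - heat_t) ** 4
    loss_heat = -(
        pos_f * (1.0 - p) ** 2 * p.log()
        + (1.0 - pos_f) * neg_w * p**2 * (1.0 - p).log()
    ).sum() * (1.0 / n_pos)

    pos_mask2 = np.repeat(pos.astype(np.float64), 2, axis=1)
    loss_size = ((pred[:, 1:3] - size_t).abs() * pos_mask2).sum() * (0.1 / n_pos)
    loss_off = ((pred[:, 3:5] - off_t).abs() * pos_mask2).sum() * (1.0 / n_pos)
    return loss_heat + loss_size + loss_off


# -- inference ----------------------------------------------------------------

def decode(pred: np.ndarray, score_threshold: float = 0.5,
           image_hw: tuple[int, int] | None = None) -> DetectionSet:
    """Peak-pick the heatmap and assemble boxes.

    Peaks are 3x3 local maxima with score strictly above the threshold.
    """
    heat = 1.0 / (1.0 + np.exp(-pred[0]))
    local_max = ndimage.maximum_filter(heat, size=3, mode="constant")
    peaks = (heat >= local_max) & (heat > score_threshold)
    ii, jj = np.nonzero(peaks)
    if len(ii) == 0:
        return DetectionSet()
    scores = heat[ii, jj]
    w = np.exp(np.clip(pred[1, ii, jj], -4, 6)) * HEAD_STRIDE
    h = np.exp(np.clip(pred[2, ii, jj], -4, 6)) * HEAD_STRIDE
    cx = (jj + pred[3, ii, jj]) * HEAD_STRIDE
    cy = (ii + pred[4, ii, jj]) * HEAD_STRIDE
    boxes = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
    if image_hw is not None:
        boxes = clip_boxes(boxes, image_hw[1], image_hw[0])
    keep = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
    return DetectionSet(boxes[keep], scores[keep])


def detect(model: DetectorModel, image: np.ndarray,
           score_threshold: float = 0.5) -> DetectionSet:
    """Run the detector on one image; every returned score exceeds the
    threshold and every box is clipped to the image bounds."""
    x = Tensor(_to_input(image))
    pred = model(x).data[0]
    return decode(pred, score_threshold, image_hw=image.shape[:2])


# -- pretraining warm-up ------------------------------------------------------

class _AutoencoderHead(Module):
    def __init__(self, in_channels: int, rng: np.random.Generator | None = None):
        self.conv = Conv2d(in_channels, 3, 3, padding=1, rng=rng)

    def forward(self, feat: Tensor, out_h: int, out_w: int) -> Tensor:
        return self.conv(F.bilinear_resize(feat, out_h, out_w))


def pretrain_backbone(cfg: DetectorConfig,
                      scenes: list[SyntheticScene]) -> dict[str, np.ndarray]:
    """Autoencoding warm-up: reconstruct scenes from the finest backbone
    level. Returns the warmed-up backbone state dict.

    Standing in for ImageNet transfer, the warm-up pool is ideally larger
    than (and disjoint from) the detection training set; pass it explicitly
    via ``train_detector(..., pretrain_scenes=...)``."""
    rng = np.random.default_rng(cfg.seed)
    backbone = Backbone(cfg.width, rng=np.random.default_rng(cfg.seed))
    head = _AutoencoderHead(backbone.out_channels[0],
                            rng=np.random.default_rng(cfg.seed + 1))
    opt = AdamW([{"params": backbone.parameters() + head.parameters(),
                  "lr": cfg.learning_rate, "weight_decay": cfg.weight_decay}])
    inputs = [_to_input(s.image) for s in scenes]
    for _ in range(cfg.pretrain_epochs):
        order = rng.permutation(len(inputs))
        for start in range(0, len(order), cfg.batch_size):
            batch = np.concatenate([inputs[k] for k in order[start:start + cfg.batch_size]])
            x = Tensor(batch)
            feats = backbone(x)
            recon = head(feats[0], batch.shape[2], batch.shape[3])
            loss = ((recon - x) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return backbone.state_dict()


# -- training -----------------------------------------------------------------

def _clip_gradients(model: Module, max_norm: float) -> None:
    if max_norm <= 0:
        return
    params = [p for p in model.parameters() if p.grad is not None]
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad = p.grad * scale


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_ap50: list[float] = field(default_factory=list)
    best_epoch: int = -1


def validation_ap50(model: DetectorModel, scenes: list[SyntheticScene]) -> float:
    from .metrics import ap_at
    truths = [s.boxes for s in scenes]
    dets = []
    for s in scenes:
        d = detect(model, s.image, score_threshold=0.05)
        dets.append((d.boxes, d.scores))
    if sum(len(t) for t in truths) == 0:
        return 0.0
    return ap_at(truths, dets, 0.5)


def train_detector(model: DetectorModel | None,
                   train_scenes: list[SyntheticScene],
                   val_scenes: list[SyntheticScene],
                   cfg: DetectorConfig,
                   pretrain_scenes: list[SyntheticScene] | None = None
                   ) -> tuple[DetectorModel, TrainHistory]:
    """Train with decoupled weight decay; the backbone parameter group runs
    at ``learning_rate * backbone_lr_multiplier``. Keeps the
    best-by-validation-AP50 checkpoint.

    When ``model`` is None one is built from ``cfg``, including the
    autoencoding warm-up if ``cfg.use_pretrained`` is set.
    """
    if not train_scenes or all(len(s.boxes) == 0 for s in train_scenes):
        raise ValueError("training requires at least one scene with annotations")
    if model is None:
        state = (pretrain_backbone(cfg, pretrain_scenes or train_scenes)
                 if cfg.use_pretrained else None)
        model = build_model(cfg, state)

    backbone_params = set(id(p) for p in model.backbone.parameters())
    groups = [
        {"params": model.backbone.parameters(),
         "lr": cfg.learning_rate * cfg.backbone_lr_multiplier,
         "weight_decay": cfg.weight_decay},
        {"params": [p for p in model.parameters() if id(p) not in backbone_params],
         "lr": cfg.learning_rate, "weight_decay": cfg.weight_decay},
    ]
    opt = AdamW(groups)
    rng = np.random.default_rng(cfg.seed + 101)

    inputs = [_to_input(s.image) for s in train_scenes]
    boxes = [s.boxes for s in train_scenes]
    history = TrainHistory()
    best_ap, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(inputs))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = Tensor(np.concatenate([inputs[k] for k in idx]))
            pred = model(x)
            loss = detection_loss(pred, [boxes[k] for k in idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss")
            opt.zero_grad()
            loss.backward()
            _clip_gradients(model, cfg.grad_clip_norm)
            opt.step()
            epoch_losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(epoch_losses)))
        due = (epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1
        if val_scenes and due:
            ap50 = validation_ap50(model, val_scenes)
            history.val_ap50.append(ap50)
            if ap50 >= best_ap:
                best_ap, best_state = ap50, model.state_dict()
                history.best_epoch = epoch
    if best_state is not None and val_scenes:
        model.load_state_dict(best_state)
    return model, history


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: DetectorModel, path) -> None:
    path = Path(path)
    np.savez(path, __config__=json.dumps(model.cfg.__dict__),
             **{k: v for k, v in model.state_dict().items()})


def load_checkpoint(path) -> DetectorModel:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = DetectorConfig(**json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_model(cfg)
    model.load_state_dict(state)
    return model


# -- ablation harness ---------------------------------------------------------

def standard_benchmark(n_train: int = 16, n_val: int = 20, n_pretrain: int = 48):
    """The fixed synthetic benchmark used for desk-scale ablations.

    Scenes mix small and medium objects evenly so that cross-scale fusion
    and feature calibration have measurable work to do (the finest feature
    level alone cannot size the larger objects). The three scene pools use
    fixed seed blocks, like a frozen dataset; only the training run seed
    varies between ablation repeats.

    Returns ``(train_scenes, val_scenes, pretrain_scenes, base_config)``.
    """
    from .synthetic import FieldConfig, generate_dataset
    make = lambda seed, n: generate_dataset(n, FieldConfig(
        image_size=128, n_rows=3, plants_per_row=3, min_box_side=6,
        position_jitter=0.15, small_fraction=0.5, seed=seed))
    cfg = DetectorConfig(width=4, neck_channels=8, image_size=128, epochs=48,
                         batch_size=8, learning_rate=0.02, pretrain_epochs=4,
                         val_every=4)
    return make(10, n_train), make(200, n_val), make(500, n_pretrain), cfg


ABLATION_VARIANTS = {
    "baseline": {"use_pretrained": False, "use_rscconv": False, "use_ascff": False},
    "pretrained": {"use_pretrained": True, "use_rscconv": False, "use_ascff": False},
    "pretrained+rscconv": {"use_pretrained": True, "use_rscconv": True, "use_ascff": False},
    "full": {"use_pretrained": True, "use_rscconv": True, "use_ascff": True},
}


def run_ablation(train_scenes, val_scenes, base_cfg: DetectorConfig,
                 variants: dict[str, dict] | None = None,
                 seeds: list[int] | None = None,
                 pretrain_scenes=None) -> list[dict]:
    """Train each variant under each seed; report best validation AP50."""
    variants = variants or ABLATION_VARIANTS
    seeds = seeds if seeds is not None else [base_cfg.seed]
    rows = []
    for seed in seeds:
        for name, flags in variants.items():
            cfg = replace(base_cfg, seed=seed, **flags)
            _, history = train_detector(None, train_scenes, val_scenes, cfg,
                                        pretrain_scenes=pretrain_scenes)
            rows.append({"variant": name, "seed": seed,
                         "val_ap50": max(history.val_ap50),
                         "final_loss": history.train_loss[-1]})
    return rows
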
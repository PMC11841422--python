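"""Self-calibrated convolution block and backbone patching.

The block splits its input into three branches:

1. an untouched identity branch that preserves the original response,
2. a 3x3 convolution at the original scale that refines local features, and
3. a calibration branch that upscales the map 2x with bilinear
   interpolation, convolves 3x3 in the enlarged space, and downscales back.

The three branches are fused by elementwise multiplication, so the identity
branch acts as a gate that keeps weak small-object responses from being
erased by downstream feature extraction. An optional logistic squashing of
the calibration branch (``gate_calibration``) bounds the product when
unnormalized maps would otherwise explode; it is off by default.

``patch_backbone`` swaps the single 3x3 convolution of every residual block
for such a block, value-copying the pretrained kernel into both the
refinement and the calibration convolutions.
"""

from __future__ import annotations

import logging

import numpy as np

from .nn import Conv2d, Module, Parameter, Tensor
from .nn import functional as F

logger = logging.getLogger(__name__)


class RSCConv(Module):
    """Three-branch self-calibrated convolution (drop-in for a 3x3 conv).

    The refinement kernel must map C channels to C channels so the identity
    branch can be fused elementwise.
    """

    def __init__(self, channels: int, stride: int = 1, padding: int = 1,
                 gate_calibration: bool = False,
                 rng: np.random.Generator | None = None):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if padding < 0:
            raise ValueError("padding must be non-negative")
        self.refine = Conv2d(channels, channels, 3, stride=stride, padding=padding, rng=rng)
        self.calib = Conv2d(channels, channels, 3, stride=1, padding=1, rng=rng)
        self.channels = channels
        self.stride = stride
        self.padding = padding
        self.gate_calibration = gate_calibration

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]} channels, block expects {self.channels}"
            )
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite values in input feature map")
        n, c, h, w = x.shape

        branch2 = self.refine(x)
        oh, ow = branch2.shape[2], branch2.shape[3]

        branch1 = F.bilinear_resize(x, oh, ow)

        up = F.bilinear_resize(x, 2 * h, 2 * w)
        branch3 = self.calib(up)
        branch3 = F.bilinear_resize(branch3, h, w)
        branch3 = F.bilinear_resize(branch3, oh, ow)
        if self.gate_calibration:
            branch3 = branch3.sigmoid()

        return branch1 * branch2 * branch3


def rscconv_forward(x: Tensor | np.ndarray, block: RSCConv) -> Tensor:
    """Functional entry point: apply ``block`` to ``x``."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return block(x)


def inherit_pretrained(weight: np.ndarray, bias: np.ndarray | None = None,
                       stride: int = 1, padding: int = 1,
                       gate_calibration: bool = False) -> RSCConv:
    """Build an :class:`RSCConv` whose both kernels are value-copies of a
    pretrained 3x3 kernel.

    The copies are independent: mutating one afterwards leaves the other
    unchanged. A missing bias becomes a zero bias.
    """
    weight = np.asarray(weight, dtype=np.float64)
    if weight.ndim != 4 or weight.shape[2:] != (3, 3):
        raise ValueError("donor kernel must have shape (out, in, 3, 3)")
    if weight.shape[0] != weight.shape[1]:
        raise ValueError("donor kernel must have equal input/output channel counts")
    channels = weight.shape[0]
    block = RSCConv(channels, stride=stride, padding=padding,
                    gate_calibration=gate_calibration)
    bias_arr = np.zeros(channels) if bias is None else np.asarray(bias, dtype=np.float64)
    block.refine.weight = Parameter(weight.copy())
    block.refine.bias = Parameter(bias_arr.copy())
    block.calib.weight = Parameter(weight.copy())
    block.calib.bias = Parameter(bias_arr.copy())
    return block


def patch_backbone(backbone, use_rscconv: bool = True,
                   gate_calibration: bool = False):
    """Replace each residual block's 3x3 convolution with an RSCConv.

    ``backbone`` must provide ``residual_blocks()`` yielding ``(name, block)``
    pairs where each block stores its 3x3 convolution in ``block.conv3``.
    Returns ``(backbone, report)``; the report lists every replacement as a
    JSON-serializable dict. Blocks already patched are left alone
    (idempotence); blocks lacking a 3x3 convolution are skipped with a
    warning.
    """
    report: list[dict] = []
    if not use_rscconv:
        return backbone, report
    for name, block in backbone.residual_blocks():
        conv = getattr(block, "conv3", None)
        if isinstance(conv, RSCConv):
            continue  # already patched
        if not isinstance(conv, Conv2d) or conv.kernel_size != 3:
            logger.warning("block %s has no 3x3 convolution; skipped", name)
            continue
        if conv.in_channels != conv.out_channels:
            logger.warning("block %s has a channel-asymmetric 3x3 convolution; skipped", name)
            continue
        bias = conv.bias.data if conv.bias is not None else None
        block.conv3 = inherit_pretrained(
            conv.weight.data, bias, stride=conv.stride, padding=conv.padding,
            gate_calibration=gate_calibration,
        )
        report.append({
            "layer": name,
            "channels": conv.in_channels,
            "stride": conv.stride,
            "params_added": patch_param_delta(conv.in_channels),
        })
    return backbone, report


def patch_param_delta(channels: int) -> int:
    """Parameters added by one replacement: one extra 3x3 kernel plus bias."""
    return channels * channels * 9 + channels
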
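"""Array-level neural primitives: 2-D convolution and bilinear resizing.

Both are implemented as custom autodiff nodes: convolution via im2col with a
col2im backward, resizing via fixed 1-D interpolation matrices whose adjoint
is the exact gradient (bilinear resampling is a linear map).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return cols, oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with OIKK weights."""
    if x.shape[1] != weight.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]} channels, "
            f"kernel expects {weight.shape[1]}"
        )
    kh, kw = weight.shape[2], weight.shape[3]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    out_data = np.einsum("ockl,ncklhw->nohw", weight.data, cols, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(grad):
        d_w = np.einsum("nohw,ncklhw->ockl", grad, cols, optimize=True)
        d_cols = np.einsum("nohw,ockl->ncklhw", grad, weight.data, optimize=True)
        n, c, h, w = x.shape
        hp, wp = h + 2 * padding, w + 2 * padding
        d_xp = np.zeros((n, c, hp, wp))
        for i in range(kh):
            for j in range(kw):
                d_xp[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += d_cols[:, :, i, j]
        d_x = d_xp[:, :, padding:padding + h, padding:padding + w] if padding else d_xp
        if bias is None:
            return (d_x, d_w)
        return (d_x, d_w, grad.sum(axis=(0, 2, 3)))

    return x._make(out_data, parents, backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear resampling matrix (half-pixel-center convention)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Resize NCHW feature maps with bilinear interpolation.

    A no-op when the target size equals the input size. Constants are
    preserved exactly because each interpolation row sums to 1.
    """
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    wh = _interp_matrix(out_h, h)
    ww = _interp_matrix(out_w, w)
    out_data = np.einsum("ij,ncjk,lk->ncil", wh, x.data, ww, optimize=True)

    def backward(grad):
        return (np.einsum("ij,ncil,lk->ncjk", wh, grad, ww, optimize=True),)

    return x._make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC11 spatial mean."""
    return x.mean(axis=(2, 3), keepdims=True)
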
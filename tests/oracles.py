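"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit Python loops against the
mathematical definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def loop_conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
                stride: int, padding: int) -> np.ndarray:
    """Nested-loop cross-correlation, NCHW x OIKK."""
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    assert ci == c
    xp = np.zeros((n, c, h + 2 * padding, wd + 2 * padding))
    xp[:, :, padding:padding + h, padding:padding + wd] = x
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((n, o, oh, ow))
    for ni in range(n):
        for oi in range(o):
            for yi in range(oh):
                for xi in range(ow):
                    acc = 0.0
                    for ci_ in range(c):
                        for ky in range(kh):
                            for kx in range(kw):
                                acc += (xp[ni, ci_, yi * stride + ky, xi * stride + kx]
                                        * w[oi, ci_, ky, kx])
                    out[ni, oi, yi, xi] = acc + (b[oi] if b is not None else 0.0)
    return out


def loop_bilinear(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Per-pixel bilinear resampling, half-pixel-center convention."""
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x.copy()
    out = np.zeros((n, c, out_h, out_w))
    for ni in range(n):
        for ci in range(c):
            for yi in range(out_h):
                sy = min(max((yi + 0.5) * h / out_h - 0.5, 0), h - 1) if h > 1 else 0.0
                y0 = int(np.floor(sy))
                y1 = min(y0 + 1, h - 1)
                fy = sy - y0
                for xi in range(out_w):
                    sx = min(max((xi + 0.5) * w / out_w - 0.5, 0), w - 1) if w > 1 else 0.0
                    x0 = int(np.floor(sx))
                    x1 = min(x0 + 1, w - 1)
                    fx = sx - x0
                    top = x[ni, ci, y0, x0] * (1 - fx) + x[ni, ci, y0, x1] * fx
                    bot = x[ni, ci, y1, x0] * (1 - fx) + x[ni, ci, y1, x1] * fx
                    out[ni, ci, yi, xi] = top * (1 - fy) + bot * fy
    return out


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def loop_rscconv(x: np.ndarray, refine_w, refine_b, calib_w, calib_b,
                 stride: int, padding: int, gate: bool) -> np.ndarray:
    """Three-branch forward composed entirely from the loop primitives."""
    n, c, h, w = x.shape
    branch2 = loop_conv2d(x, refine_w, refine_b, stride, padding)
    oh, ow = branch2.shape[2], branch2.shape[3]
    branch1 = loop_bilinear(x, oh, ow)
    up = loop_bilinear(x, 2 * h, 2 * w)
    b3 = loop_conv2d(up, calib_w, calib_b, 1, 1)
    b3 = loop_bilinear(b3, h, w)
    b3 = loop_bilinear(b3, oh, ow)
    if gate:
        b3 = sigmoid(b3)
    return branch1 * branch2 * b3


def loop_attention(x: np.ndarray, fc1_w, fc1_b, fc2_w, fc2_b,
                   sp_w, sp_b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Channel-then-spatial attention arithmetic, fully explicit.

    Returns (channel_weights, spatial_map, output).
    """
    n, c, h, w = x.shape
    pooled = np.zeros((n, c))
    for ni in range(n):
        for ci in range(c):
            pooled[ni, ci] = x[ni, ci].sum() / (h * w)
    hidden = np.maximum(pooled @ fc1_w + fc1_b, 0.0)
    cw = sigmoid(hidden @ fc2_w + fc2_b)
    x_c = x * cw[:, :, None, None]

    mean_map = x_c.mean(axis=1, keepdims=True)
    max_map = x_c.max(axis=1, keepdims=True)
    stacked = np.concatenate([mean_map, max_map], axis=1)
    sw = sigmoid(loop_conv2d(stacked, sp_w, sp_b, 1, sp_w.shape[2] // 2))
    return cw, sw, x_c * sw


def brute_force_suppress(boxes: np.ndarray, scores: np.ndarray,
                         iou_threshold: float) -> list[int]:
    """All-pairs greedy suppression; returns kept indices into the
    score-sorted ordering."""

    def iou(a, b):
        ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
        iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
        inter = ix * iy
        ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
        return inter / ua if ua > 0 else 0.0

    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    for i in order:
        if all(iou(boxes[i], boxes[k]) <= iou_threshold for k in kept):
            kept.append(i)
    return kept


def brute_force_match(truths: np.ndarray, dets: np.ndarray, scores: np.ndarray,
                      threshold: float) -> tuple[int, int, int]:
    """Score-ordered greedy matching computed independently."""

    def iou(a, b):
        ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
        iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
        inter = ix * iy
        ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
        return inter / ua if ua > 0 else 0.0

    used = set()
    tp = 0
    for d in np.argsort(-scores, kind="stable"):
        best, best_iou = None, threshold
        for t in range(len(truths)):
            if t in used:
                continue
            v = iou(dets[d], truths[t])
            if v >= best_iou and (best is None or v > best_iou):
                best, best_iou = t, v
        if best is not None:
            used.add(best)
            tp += 1
    fp = len(dets) - tp
    fn = len(truths) - tp
    return tp, fp, fn


def reference_ap_101(matched_in_rank_order: list[bool], n_truth: int) -> float:
    """Direct enumeration of the 101-point interpolated AP."""
    tps = np.cumsum([1 if m else 0 for m in matched_in_rank_order])
    fps = np.cumsum([0 if m else 1 for m in matched_in_rank_order])
    recalls = tps / n_truth
    precisions = tps / np.maximum(tps + fps, 1)
    total = 0.0
    for g in np.linspace(0, 1, 101):
        # ceiling interpolation: max precision at any recall >= g
        cand = [p for r, p in zip(recalls, precisions) if r >= g - 1e-12]
        total += max(cand) if cand else 0.0
    return total / 101.0
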
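"""Detection and counting evaluation.

Implements greedy score-ordered matching, 101-point interpolated average
precision, the IoU-threshold sweep AP_50:95, size-stratified AP with
ignore semantics for out-of-class ground truths, and the counting metrics
R^2, RMSE, MAE and MAPE.

Size classes partition positive box areas: area <= 32^2 px is small,
32^2 < area <= 96^2 is medium, larger is large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxes import box_areas, iou_matrix, validate_boxes

SMALL_MAX_AREA = 32 * 32       # 1024 px^2
MEDIUM_MAX_AREA = 96 * 96      # 9216 px^2

IOU_SWEEP = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))  # 0.50 ... 0.95


def size_class(area: float) -> str:
    """Classify a positive box area as small / medium / large."""
    if area <= 0:
        raise ValueError("area must be positive")
    if area <= SMALL_MAX_AREA:
        return "small"
    if area <= MEDIUM_MAX_AREA:
        return "medium"
    return "large"


@dataclass
class MatchResult:
    """TP/FP/FN bookkeeping at one IoU threshold.

    ``det_matched`` / ``det_ignored`` are ordered by descending score;
    ignored detections (matched only to out-of-class truths) count as
    neither TP nor FP.
    """

    tp: int
    fp: int
    fn: int
    det_matched: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    det_ignored: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_truth: int = 0

    def __post_init__(self):
        if self.tp + self.fn != self.n_truth:
            raise ValueError("TP + FN must equal the ground-truth count")


def match_detections(truth_boxes, det_boxes, det_scores,
                     iou_threshold: float = 0.5,
                     truth_ignore=None) -> MatchResult:
    """Greedily match detections to ground truths at one IoU threshold.

    Detections are processed in descending score order; each is assigned to
    the not-yet-matched eligible truth of highest IoU at or above the
    threshold. Detections whose only match is an ignored truth are flagged
    ignored. Unmatched eligible truths are false negatives.
    """
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must lie in (0, 1)")
    truth_boxes = validate_boxes(truth_boxes)
    det_boxes = validate_boxes(det_boxes)
    det_scores = np.asarray(det_scores, dtype=np.float64).ravel()
    if len(det_scores) != len(det_boxes):
        raise ValueError("scores and boxes disagree in length")
    ignore = (np.zeros(len(truth_boxes), bool) if truth_ignore is None
              else np.asarray(truth_ignore, bool))

    order = np.argsort(-det_scores, kind="stable")
    iou = iou_matrix(det_boxes, truth_boxes)

    truth_taken = np.zeros(len(truth_boxes), bool)
    matched = np.zeros(len(det_boxes), bool)
    ignored = np.zeros(len(det_boxes), bool)
    for rank, d in enumerate(order):
        eligible = ~ignore & ~truth_taken
        if eligible.any():
            cand = np.where(eligible)[0]
            best = cand[np.argmax(iou[d, cand])]
            if iou[d, best] >= iou_threshold:
                truth_taken[best] = True
                matched[rank] = True
                continue
        # may still overlap an ignored truth -> neither TP nor FP
        if ignore.any() and (iou[d, ignore] >= iou_threshold).any():
            ignored[rank] = True

    n_truth = int((~ignore).sum())
    tp = int(matched.sum())
    fp = int((~matched & ~ignored).sum())
    return MatchResult(tp=tp, fp=fp, fn=n_truth - tp,
                       det_matched=matched, det_ignored=ignored,
                       scores=det_scores[order], n_truth=n_truth)


def merge_matches(results: list[MatchResult]) -> MatchResult:
    """Pool per-image match results into one score-ranked result."""
    if not results:
        raise ValueError("nothing to merge")
    scores = np.concatenate([r.scores for r in results])
    matched = np.concatenate([r.det_matched for r in results])
    ignored = np.concatenate([r.det_ignored for r in results])
    order = np.argsort(-scores, kind="stable")
    n_truth = sum(r.n_truth for r in results)
    tp = int(matched.sum())
    return MatchResult(tp=tp, fp=int((~matched & ~ignored).sum()),
                       fn=n_truth - tp, det_matched=matched[order],
                       det_ignored=ignored[order], scores=scores[order],
                       n_truth=n_truth)


@dataclass
class PRCurve:
    recall_grid: np.ndarray
    precision: np.ndarray  # ceiling-interpolated, non-increasing

    def __post_init__(self):
        if ((self.precision < 0) | (self.precision > 1)).any():
            raise ValueError("precision values must lie in [0, 1]")


def pr_and_ap(mr: MatchResult, interpolation: str = "101point") -> tuple[PRCurve, float]:
    """Precision-recall curve and average precision from ranked matches.

    ``interpolation='101point'`` evaluates the ceiling-interpolated
    precision on the recall grid {0, 0.01, ..., 1} and averages
    (the COCO convention); ``'continuous'`` integrates the interpolated
    curve exactly over recall.
    """
    grid = np.linspace(0, 1, 101)
    if mr.n_truth == 0:
        warnings.warn("no ground-truth objects: recall undefined, AP reported as 0")
        return PRCurve(grid, np.zeros(101)), 0.0

    keep = ~mr.det_ignored
    matched = mr.det_matched[keep]
    tp_cum = np.cumsum(matched)
    fp_cum = np.cumsum(~matched)
    recall = tp_cum / mr.n_truth
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)

    # ceiling-to-the-right interpolation
    prec_interp = precision.copy()
    for i in range(len(prec_interp) - 2, -1, -1):
        prec_interp[i] = max(prec_interp[i], prec_interp[i + 1])

    if interpolation == "101point":
        idx = np.searchsorted(recall, grid, side="left")
        on_grid = np.where(idx < len(prec_interp), prec_interp[np.minimum(idx, max(len(prec_interp) - 1, 0))], 0.0)
        if len(prec_interp) == 0:
            on_grid = np.zeros(101)
        ap = float(on_grid.mean())
        return PRCurve(grid, on_grid), ap
    if interpolation == "continuous":
        r = np.concatenate([[0.0], recall])
        p = np.concatenate([[prec_interp[0] if len(prec_interp) else 0.0], prec_interp])
        ap = float(np.sum(np.diff(r) * p[1:]))
        idx = np.searchsorted(recall, grid, side="left")
        on_grid = np.where(idx < len(prec_interp), prec_interp[np.minimum(idx, max(len(prec_interp) - 1, 0))], 0.0)
        return PRCurve(grid, on_grid), ap
    raise ValueError(f"unknown interpolation {interpolation!r}")


def ap_at(truths_by_image: list, dets_by_image: list, iou_threshold: float,
          truth_ignore_by_image: list | None = None,
          interpolation: str = "101point") -> float:
    """Dataset-level AP at one IoU threshold.

    ``dets_by_image`` entries are ``(boxes, scores)`` tuples.
    """
    ignores = truth_ignore_by_image or [None] * len(truths_by_image)
    results = [match_detections(t, b, s, iou_threshold, ig)
               for t, (b, s), ig in zip(truths_by_image, dets_by_image, ignores)]
    _, ap = pr_and_ap(merge_matches(results), interpolation)
    return ap


def ap_range(ap_by_threshold: dict[float, float] | list[float]) -> float:
    """Mean AP over the ten-threshold IoU sweep 0.50, 0.55, ..., 0.95."""
    if isinstance(ap_by_threshold, dict):
        if set(np.round(list(ap_by_threshold), 2)) != set(IOU_SWEEP):
            raise ValueError("expected AP values at IoU 0.50, 0.55, ..., 0.95")
        values = [ap_by_threshold[t] for t in sorted(ap_by_threshold)]
    else:
        values = list(ap_by_threshold)
    if len(values) != 10:
        raise ValueError("expected exactly 10 AP values")
    return float(np.mean(values))


def ap_sweep(truths_by_image, dets_by_image,
             truth_ignore_by_image=None) -> dict[float, float]:
    return {t: ap_at(truths_by_image, dets_by_image, t, truth_ignore_by_image)
            for t in IOU_SWEEP}


def ap_by_size(truths_by_image, dets_by_image) -> dict[str, float | None]:
    """AP_50:95 restricted to small / medium ground truths.

    Out-of-class truths become ignore regions: detections matching them are
    dropped from the ranking instead of counted as false positives. A class
    with no ground truths anywhere is reported as ``None``.
    """
    out: dict[str, float | None] = {}
    for cls in ("small", "medium"):
        ignores, any_in_class = [], False
        for truths in truths_by_image:
            areas = box_areas(validate_boxes(truths))
            mask = np.array([size_class(a) != cls for a in areas], bool)
            any_in_class |= bool((~mask).any())
            ignores.append(mask)
        if not any_in_class:
            warnings.warn(f"no {cls} ground truths; AP omitted")
            out[cls] = None
            continue
        sweep = ap_sweep(truths_by_image, dets_by_image, ignores)
        out[cls] = ap_range(sweep)
    return out


def mean_recall(truths_by_image, dets_by_image,
                iou_thresholds=IOU_SWEEP) -> float:
    """Recall averaged over the IoU sweep (all detections considered)."""
    recalls = []
    for t in iou_thresholds:
        results = [match_detections(tr, b, s, t)
                   for tr, (b, s) in zip(truths_by_image, dets_by_image)]
        merged = merge_matches(results)
        recalls.append(merged.tp / merged.n_truth if merged.n_truth else 0.0)
    return float(np.mean(recalls))


@dataclass
class CountSeries:
    """Per-image (true count, predicted count) pairs."""

    true_counts: np.ndarray
    predicted_counts: np.ndarray

    def __post_init__(self):
        self.true_counts = np.asarray(self.true_counts, dtype=np.float64).ravel()
        self.predicted_counts = np.asarray(self.predicted_counts, dtype=np.float64).ravel()
        if len(self.true_counts) != len(self.predicted_counts):
            raise ValueError("count series lengths differ")
        if len(self.true_counts) < 1:
            raise ValueError("need at least one image")
        if (self.true_counts < 0).any() or (self.predicted_counts < 0).any():
            raise ValueError("counts must be non-negative")


def count_metrics(cs: CountSeries) -> dict[str, float | None]:
    """R^2, RMSE, MAE and MAPE of predicted vs true per-image counts.

    R^2 is ``None`` when all true counts are equal (zero variance); MAPE is
    ``None`` when any true count is zero.
    """
    m, p = cs.true_counts, cs.predicted_counts
    n = len(m)
    sq_err = np.sum((m - p) ** 2)
    rmse = float(np.sqrt(sq_err / n))
    mae = float(np.sum(np.abs(m - p)) / n)

    ss_tot = np.sum((m - m.mean()) ** 2)
    if ss_tot == 0:
        warnings.warn("all true counts equal: R^2 undefined")
        r2 = None
    else:
        r2 = float(1.0 - sq_err / ss_tot)

    if (m == 0).any():
        warnings.warn("zero true count present: MAPE undefined")
        mape = None
    else:
        mape = float(np.sum(np.abs((m - p) / m)) / n * 100.0)

    return {"r2": r2, "rmse": rmse, "mae": mae, "mape": mape}


def evaluation_report(truths_by_image, dets_by_image,
                      count_series: CountSeries | None = None) -> dict:
    """Full metric table: recall, AP_50:95, AP_S, AP_M (+ counting metrics)."""
    sweep = ap_sweep(truths_by_image, dets_by_image)
    by_size = ap_by_size(truths_by_image, dets_by_image)
    report = {
        "recall": mean_recall(truths_by_image, dets_by_image),
        "ap_50": sweep[0.5],
        "ap_50_95": ap_range(sweep),
        "ap_small": by_size["small"],
        "ap_medium": by_size["medium"],
    }
    if count_series is not None:
        report.update(count_metrics(count_series))
    return report
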
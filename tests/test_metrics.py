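"""Evaluation metrics: hand-arithmetic fixtures, brute-force matcher and AP
oracles, invariants, and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedlingcounter.metrics import (IOU_SWEEP, CountSeries, MatchResult,
                                     ap_by_size, ap_range, ap_sweep, ap_at,
                                     count_metrics, evaluation_report,
                                     match_detections, merge_matches,
                                     pr_and_ap, size_class)

from .oracles import brute_force_match, reference_ap_101


def boxes_from_grid(rng, n, span=100.0, min_side=2.0, max_side=20.0):
    x0 = rng.uniform(0, span - max_side, n)
    y0 = rng.uniform(0, span - max_side, n)
    w = rng.uniform(min_side, max_side, n)
    h = rng.uniform(min_side, max_side, n)
    return np.stack([x0, y0, x0 + w, y0 + h], axis=1)


class TestSizeClass:
    def test_boundaries(self):
        assert size_class(32 * 32) == "small"
        assert size_class(33 * 33) == "medium"
        assert size_class(96 * 96) == "medium"
        assert size_class(97 * 97) == "large"

    def test_partition_exhaustive_and_exclusive(self, rng):
        for area in rng.uniform(1e-3, 2e4, 200):
            assert size_class(area) in ("small", "medium", "large")

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            size_class(0)


class TestMatching:
    def test_identical_box_is_tp(self):
        t = [[0, 0, 10, 10]]
        mr = match_detections(t, [[0, 0, 10, 10]], [0.9], 0.99)
        assert (mr.tp, mr.fp, mr.fn) == (1, 0, 0)

    def test_single_match_rule(self):
        t = [[0, 0, 10, 10]]
        d = [[0, 0, 10, 10], [1, 1, 10, 10]]
        mr = match_detections(t, d, [0.9, 0.8], 0.5)
        assert (mr.tp, mr.fp, mr.fn) == (1, 1, 0)

    def test_invariants_hold(self, rng):
        t = boxes_from_grid(rng, 12)
        d = boxes_from_grid(rng, 15)
        mr = match_detections(t, d, rng.uniform(size=15), 0.5)
        assert mr.tp + mr.fn == len(t)
        assert mr.tp + mr.fp == len(d)

    def test_matches_brute_force_oracle(self):
        for seed in range(30):
            r = np.random.default_rng(seed)
            t = boxes_from_grid(r, int(r.integers(1, 12)), span=60, max_side=25)
            d = boxes_from_grid(r, int(r.integers(1, 20)), span=60, max_side=25)
            scores = r.uniform(size=len(d))
            for thr in (0.3, 0.5, 0.75):
                mr = match_detections(t, d, scores, thr)
                expected = brute_force_match(t, d, scores, thr)
                assert (mr.tp, mr.fp, mr.fn) == expected, f"seed={seed} thr={thr}"

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_detections([[0, 0, 1, 1]], [[0, 0, 1, 1]], [0.5], 1.0)


class TestPRAndAP:
    def test_perfect_single_detection(self):
        mr = match_detections([[0, 0, 10, 10]], [[0, 0, 10, 10]], [0.9], 0.5)
        curve, ap = pr_and_ap(mr)
        assert ap == 1.0
        assert (np.diff(curve.precision) <= 1e-12).all()

    def test_recall_precision_arithmetic(self):
        # TP=7, FN=3 -> recall 0.7; TP=7, FP=3 -> precision 0.7
        mr = MatchResult(tp=7, fp=3, fn=3,
                         det_matched=np.array([True] * 7 + [False] * 3),
                         det_ignored=np.zeros(10, bool),
                         scores=np.linspace(1, 0.1, 10), n_truth=10)
        recall = mr.tp / (mr.tp + mr.fn)
        precision = mr.tp / (mr.tp + mr.fp)
        assert recall == pytest.approx(0.7, abs=1e-12)
        assert precision == pytest.approx(0.7, abs=1e-12)

    def test_ranked_list_matches_reference_enumeration(self):
        # ranked (hit, miss, hit) over 2 truths
        mr = MatchResult(tp=2, fp=1, fn=0,
                         det_matched=np.array([True, False, True]),
                         det_ignored=np.zeros(3, bool),
                         scores=np.array([0.9, 0.8, 0.7]), n_truth=2)
        _, ap = pr_and_ap(mr)
        expected = reference_ap_101([True, False, True], 2)
        assert ap == pytest.approx(expected, abs=1e-9)

    def test_random_rankings_match_reference(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 15))
            n_truth = int(rng.integers(1, 10))
            flags = list(rng.random(n) < 0.5)
            flags = flags[:]
            tp = sum(flags)
            if tp > n_truth:  # cannot match more than the truths
                flags = [f and i < n_truth for i, f in enumerate(flags)]
                tp = sum(flags)
            mr = MatchResult(tp=tp, fp=n - tp, fn=n_truth - tp,
                             det_matched=np.array(flags, bool),
                             det_ignored=np.zeros(n, bool),
                             scores=np.linspace(1, 0.1, n), n_truth=n_truth)
            _, ap = pr_and_ap(mr)
            assert ap == pytest.approx(reference_ap_101(flags, n_truth), abs=1e-9)

    def test_zero_truths_warns_and_reports_zero(self):
        mr = MatchResult(tp=0, fp=1, fn=0, det_matched=np.array([False]),
                         det_ignored=np.zeros(1, bool),
                         scores=np.array([0.5]), n_truth=0)
        with pytest.warns(UserWarning, match="no ground-truth"):
            _, ap = pr_and_ap(mr)
        assert ap == 0.0


class TestAPRange:
    def test_constant_vector(self):
        assert ap_range([0.6] * 10) == pytest.approx(0.6, abs=1e-12)

    def test_linear_values(self):
        assert ap_range(list(np.arange(0.1, 1.05, 0.1))) == pytest.approx(0.55, abs=1e-12)

    def test_dict_pairing_is_order_free(self, rng):
        values = dict(zip(IOU_SWEEP, rng.uniform(size=10)))
        shuffled = dict(sorted(values.items(), key=lambda kv: rng.random()))
        assert ap_range(values) == pytest.approx(ap_range(shuffled), abs=1e-15)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            ap_range([0.5] * 9)

    def test_monotone_in_iou_threshold(self, rng):
        truths = [boxes_from_grid(rng, 8, span=80)]
        jitter = rng.normal(0, 1.0, size=(8, 4))
        dets = [(truths[0] + jitter, rng.uniform(0.5, 1.0, 8))]
        sweep = ap_sweep(truths, dets)
        values = [sweep[t] for t in sorted(sweep)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        assert all(0 <= v <= 1 for v in values)


class TestAPBySize:
    def test_all_small_perfect(self):
        truths = [np.array([[0, 0, 10, 10], [20, 20, 30, 30]])]
        dets = [(truths[0].copy(), np.array([0.9, 0.8]))]
        with pytest.warns(UserWarning, match="no medium"):
            out = ap_by_size(truths, dets)
        assert out["small"] == pytest.approx(1.0)
        assert out["medium"] is None

    def test_subset_equivalence(self, rng):
        """Per-class AP equals AP on the class-filtered subset when
        detections split cleanly by class."""
        small = boxes_from_grid(rng, 6, span=100, min_side=4, max_side=20)
        medium = boxes_from_grid(rng, 4, span=100, min_side=40, max_side=60)
        truths = [np.concatenate([small, medium])]
        det_boxes = np.concatenate([small, medium])
        scores = rng.uniform(0.2, 1.0, len(det_boxes))
        out = ap_by_size(truths, [(det_boxes, scores)])

        small_only = ap_range(ap_sweep([small], [(small, scores[:6])]))
        medium_only = ap_range(ap_sweep([medium], [(medium, scores[6:])]))
        assert out["small"] == pytest.approx(small_only, abs=1e-9)
        assert out["medium"] == pytest.approx(medium_only, abs=1e-9)

    def test_out_of_class_matches_are_ignored_not_fp(self):
        truths = [np.array([[0, 0, 10, 10], [50, 50, 90, 90]])]  # small + medium
        dets = [(truths[0].copy(), np.array([0.9, 0.8]))]
        out = ap_by_size(truths, dets)
        # each class sees one perfect detection and one ignored detection
        assert out["small"] == pytest.approx(1.0)
        assert out["medium"] == pytest.approx(1.0)


class TestCountMetrics:
    def test_perfect_prediction(self):
        m = count_metrics(CountSeries([5, 9, 13], [5, 9, 13]))
        assert m["r2"] == pytest.approx(1.0, abs=1e-12)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert m["mae"] == pytest.approx(0.0, abs=1e-12)
        assert m["mape"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_prediction_gives_zero_r2(self):
        truths = np.array([4, 8, 12])
        m = count_metrics(CountSeries(truths, np.full(3, truths.mean())))
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_fixture(self):
        m = count_metrics(CountSeries([10, 20], [9, 22]))
        assert m["mae"] == pytest.approx(1.5, abs=1e-12)
        assert m["rmse"] == pytest.approx(np.sqrt(2.5), abs=1e-12)
        assert m["mape"] == pytest.approx(10.0, abs=1e-12)
        assert m["r2"] == pytest.approx(0.9, abs=1e-12)

    def test_constant_truths_undefined_r2(self):
        with pytest.warns(UserWarning, match="R\\^2 undefined"):
            m = count_metrics(CountSeries([5, 5, 5], [4, 5, 6]))
        assert m["r2"] is None

    def test_zero_truth_undefined_mape(self):
        with pytest.warns(UserWarning, match="MAPE undefined"):
            m = count_metrics(CountSeries([0, 5], [1, 5]))
        assert m["mape"] is None
        assert m["mae"] is not None

    @given(st.lists(st.tuples(st.integers(1, 200), st.integers(0, 200)),
                    min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_property_metrics_nonnegative_and_consistent(self, pairs):
        m_true = [p[0] for p in pairs]
        p_pred = [p[1] for p in pairs]
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            out = count_metrics(CountSeries(m_true, p_pred))
        assert out["rmse"] >= out["mae"] - 1e-9  # RMSE dominates MAE
        assert out["mae"] >= 0 and out["rmse"] >= 0
        if out["r2"] is not None:
            assert out["r2"] <= 1.0 + 1e-12


class TestEvaluationReport:
    def test_full_table_for_perfect_detections(self, rng):
        truths = [boxes_from_grid(rng, n, span=60, min_side=4, max_side=20)
                  for n in (3, 5, 7, 4)]
        dets = [(t.copy(), np.linspace(0.95, 0.6, len(t))) for t in truths]
        counts = CountSeries([len(t) for t in truths], [len(t) for t in truths])
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            report = evaluation_report(truths, dets, counts)
        assert report["ap_50_95"] == pytest.approx(1.0)
        assert report["recall"] == pytest.approx(1.0)
        assert report["r2"] == pytest.approx(1.0)
        assert report["rmse"] == 0.0
        assert set(report) >= {"recall", "ap_50", "ap_50_95", "ap_small",
                               "ap_medium", "r2", "rmse", "mae", "mape"}


class TestMergeMatches:
    def test_pooled_counts(self, rng):
        results = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            t = boxes_from_grid(r, 5, span=50)
            d = boxes_from_grid(r, 6, span=50)
            results.append(match_detections(t, d, r.uniform(size=6), 0.5))
        merged = merge_matches(results)
        assert merged.tp == sum(r.tp for r in results)
        assert merged.n_truth == sum(r.n_truth for r in results)
        assert (np.diff(merged.scores) <= 1e-12).all()  # sorted desc

    def test_ap_at_multi_image(self, rng):
        truths = [boxes_from_grid(rng, 4, span=40) for _ in range(3)]
        dets = [(t.copy(), np.linspace(0.9, 0.6, len(t))) for t in truths]
        assert ap_at(truths, dets, 0.5) == pytest.approx(1.0)
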
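"""Evaluation schemes: matching, tentative reclassification, probability
bounds, AP/mAP and the dual-benchmark metrics."""

import numpy as np
import pytest

from vocscan.detector import Detection
from vocscan.errors import UndefinedMetricError, ValidationError
from vocscan.evaluation import (RTRange, average_precision, compute_rt_ranges,
                                intersect_model_outputs, match_detections,
                                mean_average_precision, p_intersect, p_max_bound,
                                presence_confusion, reclassify_tentatives,
                                sensitivity, specificity)
from vocscan.io import DetectionRecord, VocAnnotation

from .oracles import ap_step_integral, mc_intersect_probability


def _ann(label, s, e, sid="S1", peak=None):
    return VocAnnotation(sid, label, s, peak if peak is not None else (s + e) // 2, e)


def _rec(label, s, e, conf=0.9, sid="S1"):
    return DetectionRecord(sid, label, s, e, conf)


class TestRTRanges:
    def test_single_occurrence_degenerate_range(self):
        ranges = compute_rt_ranges([_ann(4, 480, 520, peak=500)], {"S1": 1})
        assert ranges[(4, 1)].lo == ranges[(4, 1)].hi == 500

    def test_min_max_over_instances(self):
        anns = [_ann(2, 470, 500, sid="A", peak=480),
                _ann(2, 490, 520, sid="B", peak=500),
                _ann(2, 510, 540, sid="C", peak=520)]
        eras = {"A": 1, "B": 1, "C": 1}
        assert (compute_rt_ranges(anns, eras)[(2, 1)].lo,
                compute_rt_ranges(anns, eras)[(2, 1)].hi) == (480, 520)

    def test_eras_partition_the_instances(self):
        anns = [_ann(2, 100, 120, sid="A", peak=110),
                _ann(2, 160, 180, sid="B", peak=170)]
        ranges = compute_rt_ranges(anns, {"A": 1, "B": 2})
        assert ranges[(2, 1)].hi == 110 and ranges[(2, 2)].lo == 170


class TestMatching:
    def test_overlapping_same_label_is_tp(self):
        res = match_detections([_rec(12, 400, 430)], [_ann(12, 410, 450)])
        assert len(res.tp) == 1 and not res.fp and not res.fn

    def test_disjoint_same_label_is_fp_plus_fn(self):
        res = match_detections([_rec(12, 400, 430)], [_ann(12, 600, 640)])
        assert len(res.fp) == 1 and len(res.fn) == 1 and not res.tp

    def test_perfect_detections_no_errors(self):
        anns = [_ann(1, 100, 130), _ann(5, 300, 330)]
        recs = [_rec(1, 105, 125), _rec(5, 310, 320)]
        res = match_detections(recs, anns)
        assert not res.fp and not res.fn and len(res.tp) == 2

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            match_detections([_rec(3, 10, 20), _rec(3, 50, 60)], [])


class TestTentatives:
    def _ranges(self):
        return {6: RTRange(6, 1, 400, 440), 16: RTRange(16, 1, 800, 850)}

    def test_fp_inside_class_range_becomes_ttp(self):
        match = match_detections([_rec(6, 410, 430)], [])
        pre = [Detection(label=6, start_index=370, length=21, delta=80)]
        out = reclassify_tentatives(pre, match, self._ranges())
        assert len(out.ttp) == 1 and not out.fp

    def test_fp_outside_class_range_stays_fp(self):
        match = match_detections([_rec(6, 600, 630)], [])
        pre = [Detection(label=6, start_index=560, length=31, delta=80)]
        out = reclassify_tentatives(pre, match, self._ranges())
        assert len(out.fp) == 1 and not out.ttp

    def test_fn_with_same_class_ttp_becomes_ttn(self):
        anns = [_ann(16, 900, 940)]     # expert put it outside the usual range
        recs = [_rec(16, 810, 840)]     # system sees it inside the range
        match = match_detections(recs, anns)
        pre = [Detection(label=16, start_index=770, length=31, delta=80)]
        out = reclassify_tentatives(pre, match, self._ranges())
        assert len(out.ttp) == 1 and len(out.ttn) == 1
        assert not out.fn and not out.fp

    def test_missing_range_keeps_fp_certain(self):
        match = match_detections([_rec(9, 100, 130)], [])
        out = reclassify_tentatives([], match, self._ranges())
        assert len(out.fp) == 1

    def test_reclassification_conserves_item_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(0, 6))
            recs, anns, pre = [], [], []
            for i in range(n):
                lab = int(rng.integers(1, 8))
                s = int(rng.integers(0, 900))
                recs.append(_rec(lab, s, s + 30))
                pre.append(Detection(label=lab, start_index=max(0, s - 40),
                                     length=31, delta=80))
            seen = set()
            for _ in range(int(rng.integers(0, 6))):
                lab = int(rng.integers(1, 8))
                if lab in seen:
                    continue
                seen.add(lab)
                s = int(rng.integers(0, 900))
                anns.append(_ann(lab, s, s + 30))
            recs = [r for i, r in enumerate(recs)
                    if r.label not in {x.label for x in recs[:i]}]
            ranges = {j: RTRange(j, 1, 300, 500) for j in range(1, 8)}
            match = match_detections(recs, anns)
            out = reclassify_tentatives(pre, match, ranges)
            assert len(out.tp) + len(out.ttp) + len(out.fp) == len(recs)
            assert len(out.tp) + len(out.ttn) + len(out.fn) == len(anns)


class TestPIntersect:
    def test_point_interval(self):
        assert p_intersect(100, 0, 22500) == pytest.approx(100 / 22500)

    def test_formula_example(self):
        assert p_intersect(100, 50, 22500) == pytest.approx(150 / 22450)

    def test_degenerate_zero(self):
        assert p_intersect(0, 0, 1000) == 0.0

    def test_interval_longer_than_axis_rejected(self):
        with pytest.raises(ValueError):
            p_intersect(10, 2000, 1000)

    def test_matches_monte_carlo_placement(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            R = float(rng.integers(5000, 30000))
            range_len = float(rng.integers(20, 300))
            interval_len = float(rng.integers(10, 200))
            lo = float(rng.uniform(interval_len, R - range_len - interval_len))
            p_mc, se = mc_intersect_probability(lo, lo + range_len, interval_len,
                                                R, n_draws=200_000,
                                                seed=int(rng.integers(2**31)))
            p = p_intersect(range_len, interval_len, R)
            assert abs(p - p_mc) <= 3 * se + 1e-12


class TestPMax:
    def test_singleton_maxima(self):
        ranges = [RTRange(1, 1, 100, 200)]
        dets = [Detection(label=1, start_index=0, length=51, delta=80)]
        assert p_max_bound(ranges, dets, 22500) == \
            pytest.approx(p_intersect(100, 50, 22500))

    def test_dominates_every_pair_and_is_monotone(self):
        rng = np.random.default_rng(12)
        ranges = [RTRange(j, 1, int(lo), int(lo) + int(rng.integers(10, 200)))
                  for j, lo in enumerate(rng.integers(0, 5000, size=6), 1)]
        dets = [Detection(label=1, start_index=int(s), length=int(n), delta=80)
                for s, n in zip(rng.integers(0, 5000, size=6),
                                rng.integers(20, 100, size=6))]
        pm = p_max_bound(ranges, dets, 22500)
        for r in ranges:
            for d in dets:
                assert pm >= p_intersect(r.length, d.eRT - d.sRT, 22500) - 1e-12
        longer = dets + [Detection(label=2, start_index=0, length=300, delta=80)]
        assert p_max_bound(ranges, longer, 22500) >= pm

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            p_max_bound([], [], 1000)


class TestPresence:
    def test_categories(self):
        ranges = {3: RTRange(3, 1, 100, 150)}
        recs = [_rec(2, 500, 530), _rec(3, 110, 140)]
        anns = [_ann(1, 700, 730)]
        out = presence_confusion(recs, anns, ranges, n_target_classes=4)
        assert out[1] == "FN"          # truth only
        assert out[2] == "FP*"         # system only, no range known
        assert out[3] == "TTP*"        # system only, inside its range
        assert out[4] == "TN"          # absent from both


class TestMetrics:
    def test_published_style_sensitivity_arithmetic(self):
        counts = {"tp": 816, "ttp": 226, "fp": 2, "ttn": 18, "fn": 11}
        assert sensitivity(counts, "expert") == pytest.approx(0.9657, abs=5e-5)
        assert sensitivity(counts, "corrected") == pytest.approx(0.9896, abs=5e-5)

    def test_published_style_specificity_arithmetic(self):
        counts = {"tn": 86, "fp_star": 1, "ttp_star": 208}
        assert specificity(counts, "expert") == pytest.approx(0.2915, abs=5e-5)
        assert specificity(counts, "corrected") == pytest.approx(0.9885, abs=5e-5)

    def test_perfect_counts_give_one(self):
        assert sensitivity({"tp": 10}, "expert") == 1.0
        assert sensitivity({"tp": 10}, "corrected") == 1.0
        assert specificity({"tn": 5}, "expert") == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity({"tp": 0, "fn": 0, "ttn": 0}, "expert")
        with pytest.raises(UndefinedMetricError):
            specificity({}, "corrected")

    def test_corrected_never_below_expert_on_random_counts(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            counts = {k: int(rng.integers(0, 50))
                      for k in ("tp", "ttp", "fp", "ttn", "fn")}
            if counts["tp"] + counts["fn"] + counts["ttn"] == 0:
                continue
            if counts["tp"] + counts["ttp"] + counts["fn"] == 0:
                continue
            e = sensitivity(counts, "expert")
            c = sensitivity(counts, "corrected")
            assert 0.0 <= e <= c <= 1.0


class TestAveragePrecision:
    def test_all_tp_is_one(self):
        entries = [(0.9, True), (0.8, True), (0.7, True)]
        assert average_precision(entries, 3) == 1.0

    def test_single_fp_is_zero(self):
        assert average_precision([(0.9, False)], 1) == 0.0

    def test_tp_fp_tp_hand_case(self):
        entries = [(0.9, True), (0.8, False), (0.7, True)]
        assert average_precision(entries, 2) == pytest.approx(5 / 6)

    def test_matches_step_integral_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            entries = [(float(rng.random()), bool(rng.random() < 0.6))
                       for _ in range(n)]
            n_tp = sum(t for _, t in entries)
            n_pos = n_tp + int(rng.integers(0, 5))
            if n_pos == 0:
                continue
            assert average_precision(entries, n_pos) == pytest.approx(
                ap_step_integral(entries, n_pos), abs=1e-9)

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([(0.5, True)], 0)


class TestMAP:
    def test_simple_means(self):
        assert mean_average_precision({1: 1.0, 2: 0.5}) == pytest.approx(0.75)
        assert mean_average_precision([1.0, 1.0, 1.0]) == 1.0

    def test_matches_arithmetic_mean_oracle(self):
        rng = np.random.default_rng(15)
        aps = {j: float(rng.random()) for j in range(1, 12)}
        assert mean_average_precision(aps) == pytest.approx(
            sum(aps.values()) / len(aps))

    def test_no_defined_ap_raises(self):
        with pytest.raises(UndefinedMetricError):
            mean_average_precision({})


class TestIntersection:
    def test_identical_lists_unchanged(self):
        recs = [_rec(1, 100, 130, 0.8), _rec(2, 300, 330, 0.9)]
        assert intersect_model_outputs([recs, list(recs)]) == recs

    def test_label_missing_from_one_list_dropped(self):
        a = [_rec(1, 100, 130), _rec(2, 300, 330)]
        b = [_rec(1, 105, 135)]
        out = intersect_model_outputs([a, b])
        assert [r.label for r in out] == [1]

    def test_shifted_overlap_intersected(self):
        a = [_rec(4, 100, 140, 0.8)]
        b = [_rec(4, 120, 160, 0.6)]
        [r] = intersect_model_outputs([a, b])
        assert (r.sRT, r.eRT) == (120, 140)
        assert r.confidence == pytest.approx(0.7)

    def test_disjoint_intervals_dropped(self):
        a = [_rec(4, 100, 140)]
        b = [_rec(4, 200, 260)]
        assert intersect_model_outputs([a, b]) == []
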
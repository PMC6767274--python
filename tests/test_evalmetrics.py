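import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vfssdet.detect import DetectionInterval
from vfssdet.errors import ContractError
from vfssdet.evalmetrics import (GroundTruthInterval, detection_time_error,
                                 match_detections, merge_annotations,
                                 miss_rate, precision_recall_f1, round_half_up,
                                 temporal_iou, MatchResult)

from oracles import iou_frames, match_detections_ref

intervals = st.tuples(st.integers(0, 80), st.integers(0, 40)).map(
    lambda t: (t[0], t[0] + t[1]))


def det(s, e, conf, vid=""):
    return DetectionInterval(s, e, conf, vid)


def gt(s, e, vid=""):
    return GroundTruthInterval(s, e, vid)


class TestTemporalIou:
    def test_identical(self):
        assert temporal_iou((10, 19), (10, 19)) == 1.0

    def test_disjoint(self):
        assert temporal_iou((0, 9), (20, 29)) == 0.0

    def test_partial_overlap(self):
        assert temporal_iou((0, 9), (5, 14)) == pytest.approx(5 / 15)

    def test_single_frame_intervals(self):
        assert temporal_iou((4, 4), (4, 4)) == 1.0
        assert temporal_iou((4, 4), (5, 5)) == 0.0

    @given(intervals, intervals)
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_symmetric_bounded_and_exact(self, a, b):
        v = temporal_iou(a, b)
        assert v == temporal_iou(b, a)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(float(iou_frames(a, b)))
        assert (v == 1.0) == (a == b)


class TestMatchDetections:
    def test_perfect_single_detection(self):
        r = match_detections([det(10, 20, 0.9)], [gt(10, 20)])
        assert len(r.tp_pairs) == 1 and not r.fp and not r.fn and not r.ignored

    def test_duplicate_detection_is_ignored_not_fp(self):
        r = match_detections([det(10, 20, 0.9), det(11, 21, 0.8)],
                             [gt(10, 20)])
        assert len(r.tp_pairs) == 1
        assert r.tp_pairs[0][0].confidence == 0.9
        assert len(r.ignored) == 1 and not r.fp

    def test_no_overlap_is_fp(self):
        r = match_detections([det(50, 60, 0.9)], [gt(0, 10)])
        assert len(r.fp) == 1 and len(r.fn) == 1

    def test_three_events_three_detections(self):
        gts = [gt(10, 25), gt(50, 65), gt(90, 105)]
        dets = [det(12, 27, 0.7), det(48, 60, 0.9), det(92, 110, 0.8)]
        r = match_detections(dets, gts)
        assert len(r.tp_pairs) == 3 and not r.fp and not r.fn
        r2 = match_detections(dets[:2], gts)
        assert len(r2.tp_pairs) == 2 and len(r2.fn) == 1

    def test_mismatched_video_ids_rejected(self):
        with pytest.raises(ContractError):
            match_detections([det(0, 5, 0.9, "a")], [gt(0, 5, "b")])

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_literal_reference(self, seed):
        rng = np.random.default_rng(seed)
        nd, ng = int(rng.integers(0, 7)), int(rng.integers(0, 7))
        dets, gtt = [], []
        for _ in range(nd):
            s = int(rng.integers(0, 60))
            dets.append((s, s + int(rng.integers(0, 30)),
                         round(float(rng.random()), 3)))
        for _ in range(ng):
            s = int(rng.integers(0, 60))
            gtt.append((s, s + int(rng.integers(0, 30))))
        r = match_detections([det(*d) for d in dets],
                             [gt(*g) for g in gtt])
        tp, fp, ignored, fn, _ = match_detections_ref(dets, gtt, 0.3, 15)
        assert (len(r.tp_pairs), len(r.fp), len(r.ignored), len(r.fn)) \
            == (tp, fp, ignored, fn)

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        dets = [det(int(s), int(s) + int(rng.integers(0, 25)),
                    float(rng.random()))
                for s in rng.integers(0, 80, size=rng.integers(0, 6))]
        gts = [gt(int(s), int(s) + int(rng.integers(0, 25)))
               for s in rng.integers(0, 80, size=rng.integers(0, 6))]
        r = match_detections(dets, gts)
        assert len(r.tp_pairs) + len(r.fn) == len(gts)
        assert len(r.tp_pairs) + len(r.fp) + len(r.ignored) == len(dets)


class TestMetrics:
    def test_study_scale_counts(self):
        rep = precision_recall_f1(466, 184, 157)
        d = rep.as_dict()
        assert d["precision_pct"] == 71.69
        assert d["recall_pct"] == 74.80
        assert d["f1_pct"] == 73.21

    def test_perfect_scores(self):
        rep = precision_recall_f1(5, 0, 0)
        assert rep.precision == rep.recall == rep.f1 == 1.0

    def test_undefined_metrics_warn_not_raise(self):
        with pytest.warns(UserWarning):
            rep = precision_recall_f1(0, 0, 3)
        assert np.isnan(rep.precision)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_f1_between_precision_and_recall(self, tp, fp, fn):
        if tp + fp == 0 or tp + fn == 0:
            return
        rep = precision_recall_f1(tp, fp, fn)
        if rep.precision + rep.recall > 0:
            assert min(rep.precision, rep.recall) - 1e-12 <= rep.f1
            assert rep.f1 <= max(rep.precision, rep.recall) + 1e-12


class TestTimeError:
    def test_exact_match(self):
        assert detection_time_error([(det(10, 29, 1.0), gt(10, 29))]) == 0.0

    def test_uniform_shift(self):
        err = detection_time_error([(det(10, 29, 1.0), gt(13, 32))])
        assert err == pytest.approx(0.2)

    def test_end_only_shift(self):
        err = detection_time_error([(det(10, 29, 1.0), gt(10, 35))])
        assert err == pytest.approx((0 + 3 + 6) / 3 / 15)

    def test_mean_over_pairs(self):
        pairs = [(det(10, 29, 1.0), gt(10, 29)),
                 (det(10, 29, 1.0), gt(13, 32))]
        assert detection_time_error(pairs) == pytest.approx(0.1)

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert np.isnan(detection_time_error([]))


class TestMergeAnnotations:
    def test_endpoint_means(self):
        m = merge_annotations(gt(10, 20, "v"), gt(12, 24, "v"))
        assert (m.start_frame, m.end_frame) == (11, 22)

    def test_idempotent_on_agreement(self):
        m = merge_annotations(gt(10, 20, "v"), gt(10, 20, "v"))
        assert (m.start_frame, m.end_frame) == (10, 20)

    def test_round_half_up(self):
        m = merge_annotations(gt(10, 20, "v"), gt(11, 21, "v"))
        assert (m.start_frame, m.end_frame) == (11, 21)

    def test_video_mismatch(self):
        with pytest.raises(ContractError):
            merge_annotations(gt(0, 5, "a"), gt(0, 5, "b"))


class TestMissRate:
    def _results(self, missed, total):
        out = []
        for i in range(total):
            r = MatchResult()
            if i >= missed:
                r.tp_pairs = [(det(0, 5, 1.0), gt(0, 5))]
            out.append(r)
        return out

    def test_study_scale(self):
        assert miss_rate(self._results(18, 215)) == 8.4

    def test_zero(self):
        assert miss_rate(self._results(0, 7)) == 0.0

    def test_exact_fraction(self):
        assert miss_rate(self._results(1, 8)) == 12.5


def test_report_rounding_is_half_up():
    assert round_half_up(71.685, 2) == 71.69  # repr keeps the printed digits
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(8.35, 1) == 8.4
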
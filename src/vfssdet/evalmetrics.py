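"""Detection evaluation: temporal IOU, greedy matching, and summary metrics.

Intervals are inclusive frame ranges; temporal IOU is the ratio of shared to
combined frames.  Detections are matched to ground truth greedily in
descending confidence: a detection claims the unclaimed true interval with
IOU above threshold that minimizes the start/middle/end time error; a
detection whose only above-threshold true intervals are already claimed is
ignored (it is neither correct nor spurious); one with no overlap at all is
a false positive.  Unclaimed true intervals are false negatives.  Counts are
pooled across videos (micro-averaging) before computing precision, recall
and F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ContractError

IOU_THRESHOLD = 0.3
FPS = 15.0


@dataclass
class GroundTruthInterval:
    start_frame: int
    end_frame: int
    video_id: str = ""

    def __post_init__(self):
        if self.end_frame < self.start_frame:
            raise ContractError("interval end before start")


@dataclass
class MatchResult:
    tp_pairs: list = field(default_factory=list)   # (detection, ground truth)
    fp: list = field(default_factory=list)
    fn: list = field(default_factory=list)
    ignored: list = field(default_factory=list)


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    time_error_s: float
    tp: int
    fp: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "precision_pct": round_half_up(100 * self.precision, 2),
            "recall_pct": round_half_up(100 * self.recall, 2),
            "f1_pct": round_half_up(100 * self.f1, 2),
            "time_error_s": round_half_up(self.time_error_s, 2),
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
        }


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Report rounding: ties away from zero at the requested precision."""
    if np.isnan(x):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _bounds(iv) -> tuple:
    if isinstance(iv, tuple):
        return iv
    return iv.start_frame, iv.end_frame


def temporal_iou(a, b) -> float:
    """|frames(a) & frames(b)| / |frames(a) | frames(b)| on inclusive intervals."""
    a0, a1 = _bounds(a)
    b0, b1 = _bounds(b)
    inter = min(a1, b1) - max(a0, b0) + 1
    if inter <= 0:
        return 0.0
    union = (a1 - a0 + 1) + (b1 - b0 + 1) - inter
    return inter / union


def pair_time_error(det, gt, fps: float = FPS) -> float:
    """Mean absolute start/middle/end offset in seconds for one TP pair."""
    d0, d1 = _bounds(det)
    g0, g1 = _bounds(gt)
    err_frames = (abs(d0 - g0) + abs((d0 + d1) / 2 - (g0 + g1) / 2)
                  + abs(d1 - g1)) / 3.0
    return err_frames / fps


def match_detections(dets, gts, iou_th: float = IOU_THRESHOLD,
                     fps: float = FPS) -> MatchResult:
    """Greedy confidence-ordered assignment of detections to ground truth.

    All intervals must come from a single video timeline.
    """
    vids = {d.video_id for d in dets} | {g.video_id for g in gts}
    if len(vids - {""}) > 1:
        raise ContractError(f"intervals from multiple videos: {sorted(vids)}")
    result = MatchResult()
    claimed = [False] * len(gts)
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].confidence, dets[i].start_frame))
    for i in order:
        det = dets[i]
        overlapping = [j for j, g in enumerate(gts)
                       if temporal_iou(det, g) > iou_th]
        if not overlapping:
            result.fp.append(det)
            continue
        free = [j for j in overlapping if not claimed[j]]
        if not free:
            result.ignored.append(det)
            continue
        # precedence: lowest time error, then highest IOU, then earliest start
        j = min(free, key=lambda j: (pair_time_error(det, gts[j], fps),
                                     -temporal_iou(det, gts[j]),
                                     gts[j].start_frame))
        claimed[j] = True
        result.tp_pairs.append((det, gts[j]))
    result.fn = [g for j, g in enumerate(gts) if not claimed[j]]
    return result


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return float("nan")
    return num / den


def precision_recall_f1(tp: int, fp: int, fn: int,
                        time_error_s: float = float("nan")) -> MetricsReport:
    """Precision, recall and their harmonic mean from pooled counts."""
    if min(tp, fp, fn) < 0:
        raise ContractError("counts must be non-negative")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(precision, recall, f1, time_error_s, tp, fp, fn)


def detection_time_error(tp_pairs, fps: float = FPS) -> float:
    """Mean start/middle/end time error over TP pairs, seconds."""
    if not tp_pairs:
        warnings.warn("time error undefined: no true positives", stacklevel=2)
        return float("nan")
    return float(np.mean([pair_time_error(d, g, fps) for d, g in tp_pairs]))


def merge_annotations(a: GroundTruthInterval,
                      b: GroundTruthInterval) -> GroundTruthInterval:
    """Average two annotators' endpoints for one event (round half-up)."""
    if a.video_id != b.video_id:
        raise ContractError(f"annotations from different videos: "
                            f"{a.video_id!r} vs {b.video_id!r}")
    return GroundTruthInterval(
        int(round_half_up((a.start_frame + b.start_frame) / 2, 0)),
        int(round_half_up((a.end_frame + b.end_frame) / 2, 0)),
        a.video_id,
    )


def miss_rate(per_video_results) -> float:
    """Percent of videos in which no true event was detected (1 decimal)."""
    results = list(per_video_results)
    if not results:
        raise ContractError("miss rate needs at least one video")
    missed = sum(1 for r in results if not r.tp_pairs)
    return round_half_up(100.0 * missed / len(results), 1)


def evaluate(per_video, iou_th: float = IOU_THRESHOLD,
             fps: float = FPS) -> tuple:
    """Match and pool over (detections, ground truths) per video.

    Returns (MetricsReport, list of per-video MatchResult).
    """
    matches = [match_detections(d, g, iou_th=iou_th, fps=fps)
               for d, g in per_video]
    tp_pairs = [p for m in matches for p in m.tp_pairs]
    tp = len(tp_pairs)
    fp = sum(len(m.fp) for m in matches)
    fn = sum(len(m.fn) for m in matches)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        te = detection_time_error(tp_pairs, fps) if tp_pairs else float("nan")
    report = precision_recall_f1(tp, fp, fn, time_error_s=te)
    return report, matches
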
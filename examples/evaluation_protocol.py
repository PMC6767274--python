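"""The temporal-IOU evaluation protocol on hand-built intervals.

Walks through the greedy confidence-ordered matching: a duplicate detection
of an already-claimed event is ignored (not a false positive), unmatched
detections are false positives, unmatched events are false negatives, and
the summary metrics pool the counts.
"""

from vfssdet import (DetectionInterval, GroundTruthInterval,
                     detection_time_error, match_detections, merge_annotations,
                     precision_recall_f1, temporal_iou)

# two annotators marked the same swallow slightly differently
a = GroundTruthInterval(100, 118, "vid")
b = GroundTruthInterval(104, 122, "vid")
merged = merge_annotations(a, b)
print(f"annotators [{a.start_frame},{a.end_frame}] and "
      f"[{b.start_frame},{b.end_frame}] -> ground truth "
      f"[{merged.start_frame},{merged.end_frame}]")

gts = [merged, GroundTruthInterval(200, 214, "vid")]
dets = [
    DetectionInterval(101, 121, confidence=0.95, video_id="vid"),  # good hit
    DetectionInterval(99, 125, confidence=0.80, video_id="vid"),   # duplicate
    DetectionInterval(300, 320, confidence=0.70, video_id="vid"),  # spurious
]
print(f"IOU(det1, gt1) = {temporal_iou(dets[0], gts[0]):.2f} "
      "(frames shared / frames combined)")

res = match_detections(dets, gts, iou_th=0.3)
print(f"TP={len(res.tp_pairs)}  FP={len(res.fp)}  FN={len(res.fn)}  "
      f"ignored={len(res.ignored)} (duplicate of a claimed event)")

report = precision_recall_f1(len(res.tp_pairs), len(res.fp), len(res.fn))
err = detection_time_error(res.tp_pairs, fps=15)
d = report.as_dict()
print(f"precision {d['precision_pct']}%  recall {d['recall_pct']}%  "
      f"F1 {d['f1_pct']}%  time error {err:.2f} s "
      "(mean |start/middle/end| offset)")
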
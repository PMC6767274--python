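"""Independent reference implementations used only to cross-check the package.

These are deliberately written in a different style from the library code
(python loops, frame sets, Fraction arithmetic) and stay free of any calls
into the code paths they verify.
"""

from fractions import Fraction


def iou_frames(a, b):
    """Temporal IOU via explicit frame sets."""
    sa = set(range(a[0], a[1] + 1))
    sb = set(range(b[0], b[1] + 1))
    return Fraction(len(sa & sb), len(sa | sb))


def select_candidates_ref(tally, vth, max_candidates, clip_len, seq_len):
    """Literal transcription of the selection rule.

    Visit steps in descending-tally order with earlier-step tie-break; accept
    a step if its tally strictly exceeds vth and it is not inside an already
    accepted clip; the clip start is the peak minus half a clip, clamped.
    Returns (start, end, peak) triples sorted by start.
    """
    order = sorted(range(len(tally)), key=lambda t: (-tally[t], t))
    accepted = []
    for t in order:
        if not tally[t] > vth:
            continue
        if any(s <= t <= e for s, e, _ in accepted):
            continue
        start = min(max(t - clip_len // 2, 0), seq_len - clip_len)
        accepted.append((start, start + clip_len - 1, t))
        if len(accepted) == max_candidates:
            break
    return sorted(accepted)


def extract_intervals_ref(scores, scoreth, frameth):
    """Brute force: test every (i, j) for being a kept maximal run.

    Uses a prefix count of above-threshold frames so the all-above test is
    O(1) per interval.
    """
    T = len(scores)
    above = [1 if s > scoreth else 0 for s in scores]
    prefix = [0]
    for a in above:
        prefix.append(prefix[-1] + a)
    out = []
    for i in range(T):
        for j in range(i, T):
            length = j - i + 1
            if prefix[j + 1] - prefix[i] != length:
                continue  # not all above threshold
            if i > 0 and above[i - 1]:
                continue  # extendable left: not maximal
            if j < T - 1 and above[j + 1]:
                continue  # extendable right
            if length > frameth:
                out.append((i, j))
    return out


def match_detections_ref(dets, gts, iou_th, fps):
    """Literal greedy matcher on (start, end, confidence) tuples.

    Detections are visited in descending confidence (earlier start on ties);
    each claims the unclaimed ground truth with IOU strictly above threshold
    that minimizes the start/middle/end time error, breaking ties by higher
    IOU then earlier ground-truth start.  Returns (tp, fp, ignored, fn)
    counts plus the claimed pairing.
    """

    def time_err(d, g):
        ds, de = d[0], d[1]
        gs, ge = g[0], g[1]
        return (abs(ds - gs)
                + abs(Fraction(ds + de, 2) - Fraction(gs + ge, 2))
                + abs(de - ge)) / Fraction(3) / Fraction(fps)

    order = sorted(range(len(dets)), key=lambda i: (-dets[i][2], dets[i][0]))
    claimed = {}
    fp = ignored = 0
    for i in order:
        d = dets[i]
        over = [j for j in range(len(gts))
                if iou_frames(d[:2], gts[j][:2]) > Fraction(str(iou_th))]
        if not over:
            fp += 1
            continue
        free = [j for j in over if j not in claimed]
        if not free:
            ignored += 1
            continue
        best = min(free, key=lambda j: (time_err(d, gts[j]),
                                        -iou_frames(d[:2], gts[j][:2]),
                                        gts[j][0]))
        claimed[best] = i
    tp = len(claimed)
    fn = len(gts) - tp
    return tp, fp, ignored, fn, claimed
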
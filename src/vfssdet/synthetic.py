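"""Seeded synthetic fluoroscopy-like video with known event intervals.

The generator emulates the statistical structure the cascade assumes in a
lateral swallowing exam: a static high-contrast background (bright spinal
column over a darker soft-tissue field), brief events in which a bright
bolus-like blob slides downward through the central region at a known speed,
and distractor motions — whole-frame horizontal shifts and oscillatory
vertical jitter ("coughing") with zero net displacement — that move pixels
without being events.  All magnitudes are in pixels per frame, so their
interaction with the flow-normalization threshold (|Y|/10 > 0.4 requires
> 4 px/frame) is analytically predictable.  Everything is deterministic
given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, shift as _nd_shift

from .errors import ContractError
from .evalmetrics import GroundTruthInterval
from .video_io import CLIP_LEN, FrameSequence, extract_clip

#: minimum frame gap between events (spec invariant; one clip length)
EVENT_SEPARATION = 20


@dataclass
class Distractor:
    """A non-event motion source.

    kinds: "horizontal_shift" (whole-frame lateral ramp, magnitude px/frame),
    "oscillation" (vertical jitter alternating 0/magnitude px, zero net
    displacement — below the vote threshold at the default magnitude, above
    it for hard negatives), "static_noise" (per-frame sensor noise sigma).
    """

    kind: str
    magnitude: float
    n_windows: int = 1
    window_len: int = 12


def default_distractors():
    return [
        Distractor("horizontal_shift", 6.0),
        Distractor("oscillation", 2.0),       # 2 px/frame jitter: sub-threshold
        Distractor("static_noise", 0.008),
    ]


@dataclass
class SynthSpec:
    seed: int = 0
    duration_frames: int = 90
    fps: float = 15.0
    n_events: int = 2
    event_duration_frames: tuple = (8, 20)
    event_speed_px: tuple = (5.0, 8.0)
    distractors: list = field(default_factory=default_distractors)
    background_contrast: float = 0.4
    frame_size: tuple = (224, 224)


@dataclass
class SynthGroundTruth:
    intervals: list
    event_paths: list  # per event: array of (frame, y, x) blob centers


def _background(spec: SynthSpec, rng) -> np.ndarray:
    h, w = spec.frame_size
    y, x = np.mgrid[0:h, 0:w].astype(float)
    img = 0.30 + 0.10 * (y / h)  # soft-tissue field, slightly brighter caudally
    # bright spinal column, posterior (right of center in a lateral view)
    cx = 0.72 * w
    img += spec.background_contrast * np.exp(-((x - cx) / (0.05 * w)) ** 2)
    # faint mandible/hyoid shadow anterior-superior
    img += 0.12 * np.exp(-(((y - 0.22 * h) / (0.10 * h)) ** 2
                           + ((x - 0.30 * w) / (0.14 * w)) ** 2))
    # horizontal soft-tissue boundaries (jaw line, airway wall): these give
    # the image vertical gradients, so vertical rigid motion is observable
    for cy, amp in ((0.35, 0.10), (0.55, 0.08), (0.78, 0.09)):
        img += amp * np.exp(-((y - cy * h) / (0.06 * h)) ** 2)
    # bony landmarks (vertebral corners, hyoid): trackable anchors that make
    # rigid head motion observable to the flow solver
    for ly, lx, amp in ((0.20, 0.66, 0.15), (0.42, 0.68, 0.15),
                        (0.64, 0.70, 0.15), (0.86, 0.72, 0.15),
                        (0.55, 0.35, 0.12)):
        img += amp * np.exp(-(((y - ly * h) / (0.045 * h)) ** 2
                              + ((x - lx * w) / (0.035 * w)) ** 2))
    # fixed soft texture so flow has gradients to lock onto
    img += 0.06 * gaussian_filter(rng.standard_normal((h, w)), 2.0)
    return np.clip(img, 0.0, 0.92)


def _place_windows(rng, duration, lengths, min_gap, forbidden, required=True):
    """Sample non-overlapping windows separated from ``forbidden`` intervals.

    With ``required`` unset, windows that cannot be placed are dropped
    silently (distractors are opportunistic; events are not).
    """
    if required:
        # joint placement: distribute the slack around the windows so any
        # set of lengths that fits at all is always placeable
        n = len(lengths)
        if n == 0:
            return []
        total = sum(lengths) + min_gap * (n - 1)
        slack = duration - total
        if slack < 0:
            raise ContractError(
                f"cannot place {n} separated windows in {duration} frames")
        extra = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1))
        placed, pos = [], 0
        for i, ln in enumerate(lengths):
            pos += int(extra[i])
            placed.append((pos, pos + ln - 1))
            pos += ln + min_gap
        return placed

    placed = []

    def clear(cand):
        return not any(cand[0] - min_gap <= iv[1] and iv[0] <= cand[1] + min_gap
                       for iv in placed + forbidden)

    for ln in lengths:
        ok = None
        for _ in range(50):
            if duration - ln <= 0:
                break
            s = int(rng.integers(0, duration - ln))
            if clear((s, s + ln - 1)):
                ok = (s, s + ln - 1)
                break
        if ok is None:
            feasible = [s for s in range(max(0, duration - ln))
                        if clear((s, s + ln - 1))]
            if feasible:
                s = feasible[int(rng.integers(0, len(feasible)))]
                ok = (s, s + ln - 1)
        if ok is None:
            if required:
                raise ContractError(
                    f"cannot place {len(lengths)} separated windows in "
                    f"{duration} frames")
            continue
        placed.append(ok)
    return placed


def generate_video(spec: SynthSpec):
    """Render one synthetic sequence; returns (FrameSequence, SynthGroundTruth)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    T = spec.duration_frames
    bg = _background(spec, rng)

    dlo, dhi = spec.event_duration_frames
    durations = [int(rng.integers(dlo, dhi + 1)) for _ in range(spec.n_events)]
    events = _place_windows(rng, T, durations, EVENT_SEPARATION, [])
    events.sort()

    # per-event kinematics: constant downward speed through the mid-frame
    slo, shi = spec.event_speed_px
    speeds = [float(rng.uniform(slo, shi)) for _ in events]
    paths = []
    for (s, e), v in zip(events, speeds):
        d = e - s + 1
        y0 = max(0.5 * h - v * d / 2, -0.08 * h)
        x0 = 0.48 * w + rng.uniform(-0.03, 0.03) * w
        drift = rng.uniform(-0.4, 0.4)
        paths.append(np.array([(t, y0 + v * (t - s), x0 + drift * (t - s))
                               for t in range(s, e + 1)]))

    # distractor camera offsets
    dx = np.zeros(T)
    dy = np.zeros(T)
    noise_sigma = 0.0
    forbidden = list(events)
    for d in spec.distractors:
        if d.kind == "static_noise":
            noise_sigma = d.magnitude
            continue
        wins = _place_windows(rng, T, [d.window_len] * d.n_windows, 8,
                              forbidden, required=False)
        forbidden += wins
        for (s, e) in wins:
            n = e - s + 1
            if d.kind == "horizontal_shift":
                # lateral excursion and return: head translation
                ramp = np.concatenate([np.arange(1, n // 2 + 1),
                                       np.arange(n // 2, 0, -1) - 1])[:n]
                dx[s:e + 1] += d.magnitude * ramp
            elif d.kind == "oscillation":
                dy[s:e + 1] += d.magnitude * (np.arange(n) % 2)
            else:
                raise ContractError(f"unknown distractor kind {d.kind!r}")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # bolus radii sized so the TV-L1 solver resolves the full displacement
    ry, rx = 0.11 * h, 0.08 * w
    frames = np.empty((T, h, w), dtype=np.uint8)
    for t in range(T):
        img = _nd_shift(bg, (dy[t], dx[t]), order=1, mode="nearest") \
            if (dy[t] or dx[t]) else bg.copy()
        for path in paths:
            sel = path[:, 0] == t
            if sel.any():
                _, cy, cx = path[sel][0]
                img += 0.5 * np.exp(-(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2))
        if noise_sigma:
            img = img + noise_sigma * rng.standard_normal((h, w))
        frames[t] = np.rint(np.clip(img, 0, 1) * 255).astype(np.uint8)

    seq = FrameSequence(frames[..., None], fps=spec.fps,
                        source_id=f"synth-{spec.seed}")
    gts = [GroundTruthInterval(s, e, seq.source_id) for s, e in events]
    return seq, SynthGroundTruth(gts, paths)


@dataclass
class ClipDataset:
    rgb: np.ndarray            # (N, 20, S, S, 3) float32
    labels: np.ndarray         # 0 = other, 1 = pharyngeal
    flow: np.ndarray | None = None  # (N, 20, S, S, 2) when requested


def generate_clip_dataset(n_pos: int, n_neg: int, seed: int,
                          frame_size: tuple = (64, 64),
                          event_duration_frames: tuple = (8, 12),
                          event_speed_px: tuple = (5.0, 6.5),
                          streams=("rgb",)) -> ClipDataset:
    """Balanced labeled 20-frame clips at desk scale.

    Positives are windows centered on a single synthetic event; negatives
    cycle through static background, above-threshold "coughing" oscillation
    (the hard negative: strong vertical motion, zero net displacement), and
    horizontal head shifts.
    """
    if n_pos < 1 or n_neg < 1:
        raise ContractError("need at least one clip per class")
    from .flow import compute_flow, normalize_flow

    rng = np.random.default_rng(seed)
    size = frame_size[0]
    rgb, flo, labels = [], [], []

    def emit(seq, start):
        start = int(np.clip(start, 0, len(seq) - CLIP_LEN))
        rgb.append(extract_clip(seq, start, "rgb", size=size).frames)
        if "flow" in streams:
            m = normalize_flow(compute_flow(seq))
            flo.append(extract_clip(seq, start, "flow", size=size,
                                    motion=m).frames)

    neg_kinds = ["static", "oscillation", "horizontal_shift"]
    for i in range(n_pos + n_neg):
        sub = int(rng.integers(0, 2**31 - 1))
        positive = i < n_pos
        if positive:
            spec = SynthSpec(seed=sub, duration_frames=36, n_events=1,
                             event_duration_frames=event_duration_frames,
                             event_speed_px=event_speed_px,
                             distractors=[Distractor("static_noise", 0.008)],
                             frame_size=frame_size)
            seq, gt = generate_video(spec)
            s, e = gt.intervals[0].start_frame, gt.intervals[0].end_frame
            emit(seq, (s + e) // 2 - CLIP_LEN // 2)
        else:
            kind = neg_kinds[(i - n_pos) % len(neg_kinds)]
            dis = [Distractor("static_noise", 0.008)]
            if kind == "oscillation":
                dis.append(Distractor("oscillation", 5.0, window_len=16))
            elif kind == "horizontal_shift":
                dis.append(Distractor("horizontal_shift", 6.0, window_len=16))
            spec = SynthSpec(seed=sub, duration_frames=36, n_events=0,
                             distractors=dis, frame_size=frame_size)
            seq, _ = generate_video(spec)
            emit(seq, 8)
        labels.append(1 if positive else 0)

    return ClipDataset(np.stack(rgb).astype(np.float32),
                       np.array(labels, dtype=np.int64),
                       np.stack(flo).astype(np.float32) if flo else None)
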
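"""Sliding-window detection of the pharyngeal phase in untrimmed video.

A trained clip classifier scores 20-frame windows every 5 frames; window
scores are folded to per-frame scores (mean over covering windows), smoothed
with a centered moving average, and maximal runs of frames above ``scoreth``
longer than ``frameth`` become detection intervals.  Interval confidence is
the mean run score plus a small length bonus (lambda per frame), giving a
confidence ordering for the greedy evaluation matcher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EmptyInputError
from .video_io import CLIP_LEN, FrameSequence, extract_clip

WINDOW = 20
STRIDE = 5
SCORETH = 0.5
FRAMETH = 5
LAMBDA = 0.001
SMOOTH_WIDTH = 5
PAD_FRAMES = 10


@dataclass
class WindowScore:
    window_start: int
    score: float


@dataclass
class DetectionInterval:
    start_frame: int
    end_frame: int
    confidence: float
    video_id: str = ""

    def __post_init__(self):
        if self.end_frame < self.start_frame:
            raise ValueError("interval end before start")


def window_starts(T: int, window: int = WINDOW, stride: int = STRIDE):
    """Window start indices: 0, stride, ... with the last clamped to end at T-1."""
    if T < window:
        raise EmptyInputError(f"{T} frames is shorter than the {window}-frame window")
    starts = list(range(0, T - window + 1, stride))
    if starts[-1] != T - window:
        starts.append(T - window)
    return starts


def window_scores(seq: FrameSequence, net, window: int = WINDOW,
                  stride: int = STRIDE, size: int | None = None,
                  batch_size: int = 8):
    """Classifier score for each sliding window over a sequence (rgb stream)."""
    from .net.train import PHARYNGEAL

    size = size if size is not None else net.cfg.input_size
    starts = window_starts(len(seq), window, stride)
    clips = np.stack([extract_clip(seq, s, "rgb", size=size).frames
                      for s in starts])
    probs = net.predict_proba(clips, batch_size=batch_size)[:, PHARYNGEAL]
    return [WindowScore(s, float(p)) for s, p in zip(starts, probs)]


def frame_scores(ws, T: int, window: int = WINDOW) -> np.ndarray:
    """Per-frame score: mean over covering windows.

    A frame covered by no window (possible only for exotic stride choices)
    inherits the nearest window's score.
    """
    if not ws:
        raise EmptyInputError("no window scores")
    total = np.zeros(T)
    count = np.zeros(T)
    for w in ws:
        hi = min(T, w.window_start + window)
        total[w.window_start:hi] += w.score
        count[w.window_start:hi] += 1
    covered = count > 0
    out = np.zeros(T)
    out[covered] = total[covered] / count[covered]
    if not covered.all():
        centers = np.array([w.window_start + (window - 1) / 2 for w in ws])
        scores = np.array([w.score for w in ws])
        for t in np.nonzero(~covered)[0]:
            out[t] = scores[np.argmin(np.abs(centers - t))]
    return out


def smooth_scores(s: np.ndarray, width: int = SMOOTH_WIDTH) -> np.ndarray:
    """Centered moving average with edge replication; width must be odd."""
    if width < 1 or width % 2 == 0:
        raise ConfigError(f"smoothing width must be odd and >= 1, got {width}")
    if width == 1:
        return np.asarray(s, dtype=float).copy()
    half = width // 2
    padded = np.pad(np.asarray(s, dtype=float), half, mode="edge")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def extract_intervals(s: np.ndarray, scoreth: float = SCORETH,
                      frameth: int = FRAMETH, lam: float = LAMBDA,
                      video_id: str = ""):
    """Maximal runs of frames with score > scoreth, kept if longer than frameth.

    Confidence = mean score over the run + lam * run length.  Runs touching
    the sequence end close at the last frame.
    """
    s = np.asarray(s, dtype=float)
    above = s > scoreth
    out = []
    t = 0
    T = len(s)
    while t < T:
        if above[t]:
            start = t
            while t < T and above[t]:
                t += 1
            end = t - 1
            length = end - start + 1
            if length > frameth:
                conf = float(s[start:t].mean() + lam * length)
                out.append(DetectionInterval(start, end, conf, video_id))
        else:
            t += 1
    return out


def extend_intervals(dets, pad: int = PAD_FRAMES, T: int | None = None):
    """Pad detections by ``pad`` frames on both sides (review-export aid).

    Clamped to [0, T-1]; confidences unchanged; overlaps are not merged, as
    evaluation always uses the unextended intervals.
    """
    if pad < 0:
        raise ConfigError("pad must be non-negative")
    out = []
    for d in dets:
        end = d.end_frame + pad
        if T is not None:
            end = min(end, T - 1)
        out.append(DetectionInterval(max(0, d.start_frame - pad), end,
                                     d.confidence, d.video_id))
    return out


def detect(seq: FrameSequence, net, window: int = WINDOW, stride: int = STRIDE,
           scoreth: float = SCORETH, frameth: int = FRAMETH, lam: float = LAMBDA,
           smooth_width: int = SMOOTH_WIDTH, size: int | None = None):
    """Full detection pass over one sequence: score, fold, smooth, extract."""
    ws = window_scores(seq, net, window=window, stride=stride, size=size)
    fs = frame_scores(ws, len(seq), window=window)
    sm = smooth_scores(fs, width=smooth_width)
    return extract_intervals(sm, scoreth=scoreth, frameth=frameth, lam=lam,
                             video_id=seq.source_id)
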
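"""Candidate generation: thresholded voting on vertical motion.

The pharyngeal phase shows up as brief, strong vertical motion of the bolus
through the mid-frame.  Each flow step whose maximum |Y| inside the central
region exceeds ``fth`` casts a vote on itself and its eight nearest steps
(radius 4 each side); steps whose accumulated vote exceeds ``vth`` become
peaks of 20-frame candidate clips, at most five per video, pairwise
non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, EmptyInputError
from .flow import MotionMap, compute_flow, normalize_flow
from .video_io import CLIP_LEN, Clip, FrameSequence, extract_clip

FTH = 0.4          # vote trigger on normalized |Y|
VTH = 2.5          # vote-count threshold for candidate peaks
MAX_CANDIDATES = 5
VOTE_RADIUS = 4    # "eight nearest frames": 4 on each side
CENTER_FRACTION = 0.5


@dataclass
class CandidateClip:
    """A proposed 20-frame window around a motion peak.

    ``label`` is filled at training time: "pharyngeal" if the window covers a
    true event, "other" for distractor motion.
    """

    start_frame: int
    end_frame: int
    peak_frame: int
    vote_score: float
    label: str | None = None
    rgb: np.ndarray | None = field(default=None, repr=False)
    flow: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.end_frame - self.start_frame + 1 != CLIP_LEN:
            raise ContractError("candidate clips are exactly 20 frames")
        if not self.start_frame <= self.peak_frame <= self.end_frame:
            raise ContractError("peak must lie inside the clip span")


def center_region(h: int, w: int, fraction: float = CENTER_FRACTION):
    """Inclusive (row0, row1, col0, col1) of the centered crop.

    The crop spans ``fraction`` of each dimension (rounded to integers),
    offset by floor((1-fraction)*dim/2).
    """
    if h <= 0 or w <= 0:
        raise ContractError("frame dimensions must be positive")
    if not 0 < fraction <= 1:
        raise ContractError("fraction must be in (0, 1]")

    def _bounds(dim):
        lo = int(np.floor((1 - fraction) * dim / 2))
        size = int(round(fraction * dim))
        return lo, min(lo + size, dim) - 1

    r0, r1 = _bounds(h)
    c0, c1 = _bounds(w)
    return r0, r1, c0, c1


def vote_frames(m: MotionMap, fth: float = FTH, region=None,
                radius: int = VOTE_RADIUS) -> np.ndarray:
    """Accumulate votes over flow steps.

    Each step t with max |Y| > fth inside the region adds one vote to steps
    t-radius .. t+radius (clipped to the valid range).  Returns a float vector
    of length T-1 aligned to flow-step indices.
    """
    if not m.normalized:
        raise ContractError("vote_frames requires a normalized MotionMap")
    n, h, w = m.flow.shape[:3]
    if region is None:
        region = center_region(h, w)
    r0, r1, c0, c1 = region
    peak = np.abs(m.y[:, r0:r1 + 1, c0:c1 + 1]).reshape(n, -1).max(axis=1)
    votes = np.zeros(n, dtype=np.float64)
    for t in np.nonzero(peak > fth)[0]:
        votes[max(0, t - radius):t + radius + 1] += 1.0
    return votes


def select_candidates(tally: np.ndarray, vth: float = VTH,
                      max_candidates: int = MAX_CANDIDATES,
                      clip_len: int = CLIP_LEN, seq_len: int | None = None):
    """Pick up to five non-overlapping candidate clips from a vote tally.

    Steps are visited in descending tally order (ties: earlier step first); a
    step is accepted as a peak if its tally strictly exceeds ``vth`` and it
    does not fall inside an already accepted clip's span.  The clip start is
    peak-10 clamped into the sequence.  Returned sorted by start frame.
    """
    if seq_len is None:
        seq_len = len(tally) + 1
    if seq_len < clip_len:
        raise EmptyInputError(f"sequence of {seq_len} frames is shorter than a clip")
    order = np.lexsort((np.arange(len(tally)), -tally))
    accepted: list[CandidateClip] = []
    for t in order:
        if tally[t] <= vth:
            break  # descending order: nothing later can exceed vth
        if any(c.start_frame <= t <= c.end_frame for c in accepted):
            continue
        start = int(np.clip(t - clip_len // 2, 0, seq_len - clip_len))
        accepted.append(CandidateClip(start, start + clip_len - 1, int(t),
                                      float(tally[t])))
        if len(accepted) >= max_candidates:
            break
    return sorted(accepted, key=lambda c: c.start_frame)


def harvest_candidates(seq: FrameSequence, fth: float = FTH, vth: float = VTH,
                       max_candidates: int = MAX_CANDIDATES,
                       center_fraction: float = CENTER_FRACTION,
                       radius: int = VOTE_RADIUS, motion: MotionMap | None = None,
                       **tvl1_params):
    """Run the full candidate stage on one sequence (no pixel extraction).

    Returns (candidates, normalized MotionMap); pass a precomputed ``motion``
    to skip the flow solve.
    """
    if motion is None:
        motion = normalize_flow(compute_flow(seq, **tvl1_params))
    elif not motion.normalized:
        motion = normalize_flow(motion)
    h, w = motion.flow.shape[1:3]
    tally = vote_frames(motion, fth=fth,
                        region=center_region(h, w, center_fraction),
                        radius=radius)
    cands = select_candidates(tally, vth=vth, max_candidates=max_candidates,
                              seq_len=len(seq))
    return cands, motion


def harvest_training_clips(seq: FrameSequence, size: int = 224,
                           streams=("rgb", "flow"), motion: MotionMap | None = None,
                           **params):
    """Candidate stage plus pixel/flow tensor extraction for training.

    Composes flow -> normalize -> vote -> select -> extract; each returned
    CandidateClip carries its rgb (L,size,size,3) and/or flow (L,size,size,2)
    tensor.
    """
    tvl1 = {k: params.pop(k) for k in list(params)
            if k in ("attachment", "tightness", "num_warp", "num_iter", "tol")}
    cands, motion = harvest_candidates(seq, motion=motion, **params, **tvl1)
    for c in cands:
        if "rgb" in streams:
            c.rgb = extract_clip(seq, c.start_frame, "rgb", size=size).frames
        if "flow" in streams:
            c.flow = extract_clip(seq, c.start_frame, "flow", size=size,
                                  motion=motion).frames
    return cands, motion


@dataclass
class ClipCorpusSummary:
    """Bookkeeping of a labeled candidate-clip corpus and its split."""

    n_pharyngeal: int
    n_other: int
    n_train: int
    n_val: int

    @property
    def total(self) -> int:
        return self.n_pharyngeal + self.n_other

    def consistent(self) -> bool:
        """Class counts and split counts must partition the same corpus."""
        return self.n_train + self.n_val == self.total

    @classmethod
    def from_labels(cls, labels, n_train: int) -> "ClipCorpusSummary":
        labels = list(labels)
        n_pos = sum(1 for l in labels if l in (1, "pharyngeal"))
        return cls(n_pos, len(labels) - n_pos, n_train, len(labels) - n_train)


def label_candidates(cands, gt_intervals, min_iou: float = 0.3):
    """Label candidates "pharyngeal"/"other" by temporal IOU with ground truth.

    A candidate is positive if it overlaps any true interval with IOU above
    ``min_iou`` or its peak frame lies inside a true interval.
    """
    from .evalmetrics import temporal_iou

    for c in cands:
        pos = any(
            temporal_iou((c.start_frame, c.end_frame), (g.start_frame, g.end_frame)) > min_iou
            or g.start_frame <= c.peak_frame <= g.end_frame
            for g in gt_intervals
        )
        c.label = "pharyngeal" if pos else "other"
    return cands
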
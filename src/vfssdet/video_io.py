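"""Video and interval-table I/O.

Frame sequences are the raw unit every stage consumes: ordered grayscale (or
3-channel) frames plus a frame rate.  Fluoroscopy sources are nominally 30 FPS
and are resampled to 15 FPS by uniform index subsampling before any analysis.
Intervals (candidate clips, detections, ground truth) travel as CSV or JSON
tables with 0-based inclusive frame indices.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize

from .errors import BoundsError, ContractError, EmptyInputError, VideoReadError

CLIP_LEN = 20
NET_INPUT_SIZE = 224

#: ITU-R BT.601 luma weights, used to collapse RGB input to grayscale for flow.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """Ordered frames (T, H, W, C) with FPS metadata.

    ``frames`` is either an integer array in [0, 255] or a float array in
    [0, 1]; ``pixel_scale`` records which ("uint8" or "unit").
    """

    frames: np.ndarray
    fps: float
    source_id: str = ""
    pixel_scale: str = "uint8"

    def __post_init__(self) -> None:
        if self.frames.ndim == 3:
            self.frames = self.frames[..., None]
        if self.frames.ndim != 4 or self.frames.shape[-1] not in (1, 3):
            raise ContractError(
                f"frames must be T,H,W,C with C in {{1,3}}; got {self.frames.shape}"
            )
        if len(self.frames) < 1:
            raise EmptyInputError("a FrameSequence needs at least one frame")
        if not self.fps > 0:
            raise ContractError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def to_unit(self) -> np.ndarray:
        """Frames as float64 in [0, 1]."""
        if self.pixel_scale == "unit":
            return np.asarray(self.frames, dtype=np.float64)
        return np.asarray(self.frames, dtype=np.float64) / 255.0

    def gray(self) -> np.ndarray:
        """Grayscale frames (T, H, W) in [0, 1], luma-weighted if RGB."""
        u = self.to_unit()
        if u.shape[-1] == 1:
            return u[..., 0]
        return u @ _LUMA


@dataclass
class Clip:
    """A fixed-length window ready for the classifier.

    ``frames`` is (L, H', W', C) with L=20; rgb clips carry C=3, flow clips
    C=2 (the two displacement components).
    """

    frames: np.ndarray
    start_frame: int
    stream: str

    def __post_init__(self) -> None:
        if self.stream not in ("rgb", "flow"):
            raise ContractError(f"unknown stream {self.stream!r}")
        want_c = 3 if self.stream == "rgb" else 2
        if self.frames.ndim != 4 or self.frames.shape[0] != CLIP_LEN:
            raise ContractError(
                f"clip must have exactly {CLIP_LEN} frames, got {self.frames.shape}"
            )
        if self.frames.shape[-1] != want_c:
            raise ContractError(
                f"{self.stream} clip needs C={want_c}, got {self.frames.shape[-1]}"
            )


def _resample_indices(n: int, src_fps: float, target_fps: float) -> np.ndarray:
    """Indices kept when resampling n frames from src_fps to target_fps.

    Integer downsampling ratio keeps every k-th frame; otherwise nearest-index
    selection on the uniform time grid.  Never emits more frames than exist.
    """
    if target_fps >= src_fps:
        return np.arange(n)
    ratio = src_fps / target_fps
    if abs(ratio - round(ratio)) < 1e-9:
        return np.arange(0, n, int(round(ratio)))
    n_out = int(np.floor((n - 1) / ratio)) + 1
    idx = np.rint(np.arange(n_out) * ratio).astype(int)
    return np.unique(np.clip(idx, 0, n - 1))


def resample(seq: FrameSequence, target_fps: float) -> FrameSequence:
    """Resample a sequence to target_fps by uniform index subsampling."""
    idx = _resample_indices(len(seq), seq.fps, target_fps)
    return replace(seq, frames=seq.frames[idx], fps=min(target_fps, seq.fps))


def _frame_files(path: str) -> list:
    exts = (".png", ".jpg", ".jpeg")
    names = sorted(n for n in os.listdir(path) if n.lower().endswith(exts))
    return [os.path.join(path, n) for n in names]


def read_video(path: str, target_fps: float = 15.0, source_fps: float | None = None) -> FrameSequence:
    """Read an MP4/AVI file or a directory of lexically ordered PNG/JPEG frames.

    The decoded sequence is resampled to ``target_fps`` by index subsampling.
    For frame directories, which carry no rate metadata, ``source_fps``
    defaults to ``target_fps`` (no resampling).
    """
    if os.path.isdir(path):
        files = _frame_files(path)
        if not files:
            raise EmptyInputError(f"no frames decoded from {path}")
        frames = np.stack([iio.imread(f) for f in files])
        src = source_fps if source_fps is not None else target_fps
    else:
        if not os.path.exists(path):
            raise VideoReadError(f"cannot read video {path}")
        try:
            frames = np.asarray(iio.imread(path))
            meta = iio.immeta(path)
        except Exception as e:  # decoder errors vary by backend
            raise VideoReadError(f"cannot read video {path}: {e}") from e
        if frames.size == 0:
            raise EmptyInputError(f"no frames decoded from {path}")
        src = source_fps if source_fps is not None else float(meta.get("fps", target_fps))
    if frames.ndim == 3:
        frames = frames[..., None]
    if frames.shape[-1] == 3 and np.ptp(frames, axis=-1).max() == 0:
        frames = frames[..., :1]  # gray video stored as replicated RGB
    seq = FrameSequence(frames, fps=src, source_id=os.path.basename(path.rstrip("/")))
    return resample(seq, target_fps)


def write_frames(seq: FrameSequence, out_dir: str) -> None:
    """Write a sequence as numbered PNGs (lossless round-trip path)."""
    os.makedirs(out_dir, exist_ok=True)
    frames = seq.frames
    if seq.pixel_scale == "unit":
        frames = np.rint(np.asarray(frames) * 255).astype(np.uint8)
    frames = np.asarray(frames, dtype=np.uint8)
    for t, fr in enumerate(frames):
        iio.imwrite(os.path.join(out_dir, f"frame_{t:06d}.png"), fr[..., 0] if fr.shape[-1] == 1 else fr)


def resize_frames(frames: np.ndarray, size: int) -> np.ndarray:
    """Bilinearly resize (T, H, W, C) float frames to (T, size, size, C)."""
    if frames.shape[1] == size and frames.shape[2] == size:
        return frames
    out = np.empty((frames.shape[0], size, size, frames.shape[3]), dtype=np.float64)
    for t in range(frames.shape[0]):
        out[t] = _sk_resize(frames[t], (size, size), order=1, preserve_range=True,
                            anti_aliasing=False)
    return out


def extract_clip(seq: FrameSequence, start_frame: int, stream: str = "rgb",
                 size: int = NET_INPUT_SIZE, motion=None) -> Clip:
    """Extract the 20-frame window starting at ``start_frame``.

    rgb: frames are resized to (size, size) and a single channel is replicated
    to 3.  flow: requires the sequence's MotionMap; the normalized flow steps
    covering the window are resized (values are dimensionless after the /10
    normalization, so no magnitude rescaling on resize).
    """
    T = len(seq)
    if start_frame < 0 or start_frame + CLIP_LEN > T:
        raise BoundsError(
            f"clip [{start_frame}, {start_frame + CLIP_LEN - 1}] exceeds sequence of {T} frames"
        )
    if stream == "rgb":
        window = seq.to_unit()[start_frame:start_frame + CLIP_LEN]
        window = resize_frames(window, size)
        if window.shape[-1] == 1:
            window = np.repeat(window, 3, axis=-1)
        return Clip(window.astype(np.float32), start_frame, "rgb")
    if stream == "flow":
        if motion is None:
            raise ContractError("flow clips need a MotionMap via motion=")
        if not motion.normalized:
            raise ContractError("flow clips require a normalized MotionMap")
        n_steps = motion.flow.shape[0]
        # flow step t pairs frames (t, t+1); the last frame of the window
        # reuses the final available step.
        idx = np.minimum(np.arange(start_frame, start_frame + CLIP_LEN), n_steps - 1)
        window = resize_frames(motion.flow[idx].astype(np.float64), size)
        return Clip(window.astype(np.float32), start_frame, "flow")
    raise ContractError(f"unknown stream {stream!r}")


# ---------------------------------------------------------------------------
# Interval tables

_COLUMNS = ["video_id", "start_frame", "end_frame", "confidence"]


def intervals_to_frame(records) -> pd.DataFrame:
    """Normalize a list of interval-like objects/dicts to the shared table."""
    rows = []
    for r in records:
        if isinstance(r, dict):
            d = dict(r)
        else:
            d = {
                "video_id": getattr(r, "video_id", ""),
                "start_frame": r.start_frame,
                "end_frame": r.end_frame,
            }
            if hasattr(r, "confidence"):
                d["confidence"] = r.confidence
        d.setdefault("video_id", "")
        d.setdefault("confidence", np.nan)
        rows.append({k: d[k] for k in _COLUMNS})
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df["start_frame"] = df["start_frame"].astype(int)
    df["end_frame"] = df["end_frame"].astype(int)
    return df


def write_intervals(records, path: str) -> None:
    """Write intervals as CSV or JSON (by extension)."""
    df = intervals_to_frame(records)
    if path.endswith(".json"):
        recs = df.to_dict(orient="records")
        for r in recs:
            if pd.isna(r["confidence"]):
                del r["confidence"]
        with open(path, "w") as fh:
            json.dump(recs, fh, indent=1)
    else:
        df.to_csv(path, index=False)


def read_intervals(path: str) -> pd.DataFrame:
    """Read the CSV/JSON interval dialect back into the shared table."""
    if path.endswith(".json"):
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    for col in _COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "video_id" else np.nan
    df["start_frame"] = df["start_frame"].astype(int)
    df["end_frame"] = df["end_frame"].astype(int)
    return df[_COLUMNS]
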
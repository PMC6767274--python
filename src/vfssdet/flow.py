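"""Dense TV-L1 optical flow and the truncate/normalize step.

Flow is computed between consecutive grayscale frames at native resolution.
Components follow image coordinates: X is horizontal, Y is vertical with
positive Y pointing down, so a descending bolus produces positive Y flow.
Raw displacements (pixels) are truncated to [-10, 10] and divided by 10, so
every downstream stage sees values in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.registration import optical_flow_tvl1

from .errors import ContractError, EmptyInputError
from .video_io import FrameSequence

#: Truncation bound in pixels; values are clamped to +-TRUNC then divided by it.
TRUNC = 10.0

#: Default TV-L1 solver parameters (attachment weight, tightness, warps per
#: scale, fixed-point iterations per warp, convergence tolerance).
DEFAULT_TVL1_PARAMS = dict(attachment=15.0, tightness=0.3, num_warp=5,
                           num_iter=10, tol=1e-4)


@dataclass
class MotionMap:
    """Per-frame-pair displacement fields, (T-1, H, W, 2) with channels (X, Y)."""

    flow: np.ndarray
    normalized: bool = False
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.flow.ndim != 4 or self.flow.shape[-1] != 2:
            raise ContractError(f"flow must be (T-1),H,W,2; got {self.flow.shape}")

    @property
    def y(self) -> np.ndarray:
        """Vertical component, (T-1, H, W), positive down."""
        return self.flow[..., 1]

    @property
    def x(self) -> np.ndarray:
        return self.flow[..., 0]


def compute_flow(seq: FrameSequence, **tvl1_params) -> MotionMap:
    """TV-L1 flow for every consecutive frame pair of a sequence.

    Frames are converted to grayscale (luma weighting for RGB input).  The
    result is unnormalized, in pixels, and deterministic for fixed solver
    parameters.  Keyword arguments override :data:`DEFAULT_TVL1_PARAMS`.
    """
    if len(seq) < 2:
        raise EmptyInputError("flow needs at least 2 frames")
    params = {**DEFAULT_TVL1_PARAMS, **tvl1_params}
    gray = seq.gray()
    T = gray.shape[0]
    out = np.empty((T - 1,) + gray.shape[1:] + (2,), dtype=np.float32)
    for t in range(T - 1):
        # returns (row, col) displacement, i.e. (Y, X)
        vy, vx = optical_flow_tvl1(gray[t], gray[t + 1], **params)
        out[t, ..., 0] = vx
        out[t, ..., 1] = vy
    return MotionMap(out, normalized=False, source_id=seq.source_id)


def normalize_flow(m: MotionMap) -> MotionMap:
    """Truncate components to [-10, 10] pixels and divide by 10.

    Refuses already-normalized input so the scaling can never be applied
    twice.
    """
    if m.normalized:
        raise ContractError("MotionMap is already normalized")
    scaled = np.clip(m.flow, -TRUNC, TRUNC) / TRUNC
    return replace(m, flow=scaled.astype(np.float32), normalized=True)


def save_motion(m: MotionMap, path: str) -> None:
    """Cache a MotionMap as an NPZ archive keyed by its source_id."""
    np.savez_compressed(path, flow=m.flow, normalized=m.normalized,
                        source_id=m.source_id)


def load_motion(path: str) -> MotionMap:
    with np.load(path, allow_pickle=False) as z:
        return MotionMap(z["flow"], normalized=bool(z["normalized"]),
                         source_id=str(z["source_id"]))
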
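import numpy as np
import pytest

from vfssdet.video_io import FrameSequence


@pytest.fixture
def gradient_sequence():
    """A 30-frame grayscale sequence with distinct per-frame values."""
    frames = np.arange(30, dtype=np.uint8)[:, None, None, None] * np.ones(
        (1, 16, 16, 1), dtype=np.uint8)
    return FrameSequence(frames, fps=15.0, source_id="grad")


def moving_square_pair(h=64, w=64, dy=3, dx=0, size=12):
    """Two frames with a bright square translated by (dy, dx) pixels."""
    f0 = np.full((h, w), 0.2)
    f1 = np.full((h, w), 0.2)
    r, c = h // 4, w // 2 - size // 2
    f0[r:r + size, c:c + size] = 0.9
    f1[r + dy:r + dy + size, c + dx:c + dx + size] = 0.9
    frames = np.stack([f0, f1])[..., None]
    return FrameSequence(frames, fps=15.0, source_id="square",
                         pixel_scale="unit")


@pytest.fixture(scope="session")
def tiny_trained_net():
    """A very small classifier trained on a separable toy clip set.

    Shared across tests that need any trained model; 32x32 input keeps the
    training loop fast.
    """
    from vfssdet.net import (NetworkConfig, TrainSchedule, build_network,
                             train)
    from vfssdet.synthetic import generate_clip_dataset

    ds = generate_clip_dataset(12, 12, seed=7, frame_size=(32, 32))
    cfg = NetworkConfig(variant="proposed", stream="rgb",
                        channel_schedule={"conv1": 8, "stages": (16, 16, 16, 16)},
                        input_size=32)
    net = build_network(cfg, seed=0)
    sched = TrainSchedule(total_iterations=120, warmup_iterations=20, seed=0)
    losses = train(net, ds.rgb, ds.labels, sched)
    return net, ds, losses
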
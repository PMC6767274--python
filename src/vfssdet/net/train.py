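"""Training schedule and loop for the clip classifiers.

Momentum SGD under cosine learning-rate decay with a linear warm-start ramp;
initial rate 0.1, mini-batch 6.  All randomness (weight init, batch
sampling) derives from the schedule's seed, so a fixed seed reproduces the
loss trace bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ContractError, DegenerateDataError
from .layers import softmax_cross_entropy
from .model import Network

#: class index of the pharyngeal phase in the 2-way head
PHARYNGEAL = 1
LABEL_INDEX = {"other": 0, "pharyngeal": 1}


@dataclass
class TrainSchedule:
    total_iterations: int
    warmup_iterations: int = 50
    initial_lr: float = 0.1
    batch_size: int = 6
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not self.warmup_iterations < self.total_iterations:
            raise ContractError("warmup must be shorter than the total schedule")


def cosine_lr(iteration: int, sched: TrainSchedule) -> float:
    """Learning rate at an iteration: linear ramp, then cosine decay to 0."""
    if iteration < sched.warmup_iterations:
        return sched.initial_lr * iteration / sched.warmup_iterations
    span = sched.total_iterations - sched.warmup_iterations
    p = (iteration - sched.warmup_iterations) / span
    return sched.initial_lr * 0.5 * (1.0 + np.cos(np.pi * p))


def _as_labels(labels) -> np.ndarray:
    out = np.array([LABEL_INDEX.get(l, l) for l in labels], dtype=np.int64)
    if out.min() < 0 or out.max() > 1:
        raise ContractError("labels must be other/pharyngeal (0/1)")
    return out


def train(net: Network, clips: np.ndarray, labels, sched: TrainSchedule):
    """Train in place; returns the per-iteration loss trace.

    ``clips`` is (N, L, H, W, C) channel-last; ``labels`` are 0/1 or the
    strings "other"/"pharyngeal".
    """
    y = _as_labels(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training set must contain both classes")
    clips = np.asarray(clips, dtype=np.float32)
    if len(clips) != len(y):
        raise ContractError("clips and labels length mismatch")

    rng = np.random.default_rng(sched.seed)
    net.initialize(rng)
    velocity = [np.zeros_like(p.value) for p in net.params()]
    losses = np.empty(sched.total_iterations)
    for it in range(sched.total_iterations):
        idx = rng.choice(len(y), size=min(sched.batch_size, len(y)), replace=False)
        net.zero_grad()
        logits = net.forward(clips[idx], train=True)
        loss, dlogits = softmax_cross_entropy(logits, y[idx])
        net.backward(dlogits)
        lr = cosine_lr(it, sched)
        for p, v in zip(net.params(), velocity):
            v *= sched.momentum
            v -= lr * p.grad
            p.value += v
        losses[it] = loss
    return losses


def classify_clip(net: Network, clip) -> float:
    """Probability that a clip shows the pharyngeal phase."""
    frames = clip.frames if hasattr(clip, "frames") else clip
    return float(net.predict_proba(np.asarray(frames)[None])[0, PHARYNGEAL])


def evaluate_accuracy(net: Network, clips, labels) -> float:
    """Fraction of clips assigned their true class."""
    y = _as_labels(labels)
    p = net.predict_proba(np.asarray(clips, dtype=np.float32))
    return float((p.argmax(axis=1) == y).mean())
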
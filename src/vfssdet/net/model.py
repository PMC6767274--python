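"""The two clip-classifier layouts.

Both share the inflated-Inception skeleton: a 7x7x7 stride-2 stem, spatial
pools after the early stages, spatiotemporal stride-2 pools after the later
ones, and a final average pool over the remaining 2x7x7 extent feeding a
2-way linear head.  The baseline keeps Inception-V1's stage depths (plain
convs, then 2, 5, 2 inception modules); the proposed variant replaces the
plain stage-2 convs with inception modules and deepens every stage to
3, 4, 6, 3 modules so small, fast motion is modelled earlier and longer.

Channel widths are configurable (the nominal widths of the original
architectures are not part of the printed layout); branch widths within a
module follow Inception-style proportions of the stage width W:
W/4 | W/8->W/2 | W/16->W/8 | pool->W/8, which concatenate back to W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ContractError
from .layers import (BatchNorm3d, Conv3d, GlobalAvgPool, InceptionModule,
                     Linear, MaxPool3d, ReLU, Sequential, softmax)

#: inception modules per stage (conv2..conv5); baseline stage 2 is plain convs
STAGE_COUNTS = {"baseline": (0, 2, 5, 2), "proposed": (3, 4, 6, 3)}

#: default widths: stem output channels and the four stage widths
DEFAULT_SCHEDULE = {"conv1": 32, "stages": (64, 160, 208, 240)}

#: reduced widths for desk-scale experiments
TOY_SCHEDULE = {"conv1": 8, "stages": (16, 32, 32, 32)}


def InceptionModuleSpec(width: int):
    """Branch widths for a module of total output ``width`` (divisible by 16)."""
    if width % 16:
        raise ContractError(f"stage width must be divisible by 16, got {width}")
    return (width // 4, (width // 8, width // 2),
            (width // 16, width // 8), width // 8)


@dataclass
class NetworkConfig:
    variant: str = "proposed"
    stream: str = "rgb"
    channel_schedule: dict = field(default_factory=lambda: dict(DEFAULT_SCHEDULE))
    num_classes: int = 2
    clip_len: int = 20
    input_size: int = 224

    def __post_init__(self):
        if self.variant not in STAGE_COUNTS:
            raise ContractError(f"variant must be baseline|proposed, got {self.variant}")
        if self.stream not in ("rgb", "flow"):
            raise ContractError(f"stream must be rgb|flow, got {self.stream}")

    @property
    def in_channels(self) -> int:
        return 3 if self.stream == "rgb" else 2


class Network:
    """A built clip classifier: config + layer stack + bookkeeping."""

    def __init__(self, cfg: NetworkConfig, body: Sequential):
        self.cfg = cfg
        self.body = body
        self.pre_pool_extent: tuple | None = None  # (T, H, W) seen before avgpool
        for layer in body.layers:
            if isinstance(layer, GlobalAvgPool):
                self._avgpool = layer

    def _to_internal(self, clips: np.ndarray) -> np.ndarray:
        """(N, L, H, W, C) channel-last -> (N, C, L, H, W) float32, with checks."""
        clips = np.asarray(clips, dtype=np.float32)
        if clips.ndim == 4:
            clips = clips[None]
        want = (self.cfg.clip_len, self.cfg.input_size, self.cfg.input_size,
                self.cfg.in_channels)
        if clips.shape[1:] != want:
            raise ContractError(
                f"expected clips of shape (N,)+{want}, got {clips.shape}")
        return np.ascontiguousarray(clips.transpose(0, 4, 1, 2, 3))

    def forward(self, clips: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (N, num_classes) for a batch of channel-last clips."""
        x = self._to_internal(clips)
        y = self.body.forward(x, train=train)
        self.pre_pool_extent = self._avgpool._shape[2:]
        return y

    def backward(self, dlogits: np.ndarray) -> None:
        self.body.backward(dlogits)

    def predict_proba(self, clips: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Softmax class probabilities, batched for memory."""
        clips = np.asarray(clips)
        if clips.ndim == 4:
            clips = clips[None]
        out = [softmax(self.forward(clips[i:i + batch_size]))
               for i in range(0, len(clips), batch_size)]
        return np.concatenate(out, axis=0)

    def params(self):
        return self.body.params()

    def initialize(self, rng) -> None:
        self.body.initialize(rng)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0


def build_network(cfg: NetworkConfig, seed: int = 0) -> Network:
    """Assemble the printed layer sequence for either variant."""
    n2, n3, n4, n5 = STAGE_COUNTS[cfg.variant]
    c1 = cfg.channel_schedule["conv1"]
    w2, w3, w4, w5 = cfg.channel_schedule["stages"]

    def conv_bn_relu(ci, co, k, stride=(1, 1, 1)):
        return [Conv3d(ci, co, (k,) * 3, stride), BatchNorm3d(co), ReLU()]

    def stage(cin, width, n_modules):
        layers, c = [], cin
        for _ in range(n_modules):
            layers.append(InceptionModule(c, InceptionModuleSpec(width)))
            c = width
        return layers, c

    layers = conv_bn_relu(cfg.in_channels, c1, 7, stride=(2, 2, 2))
    layers.append(MaxPool3d((1, 3, 3), (1, 2, 2)))
    if cfg.variant == "baseline":
        layers += conv_bn_relu(c1, c1, 1) + conv_bn_relu(c1, w2, 3)
        c = w2
    else:
        st, c = stage(c1, w2, n2)
        layers += st
    layers.append(MaxPool3d((1, 3, 3), (1, 2, 2)))
    st, c = stage(c, w3, n3)
    layers += st
    layers.append(MaxPool3d((3, 3, 3), (2, 2, 2)))
    st, c = stage(c, w4, n4)
    layers += st
    # no temporal padding here: 5 temporal steps pool to the printed extent 2
    layers.append(MaxPool3d((3, 3, 3), (2, 2, 2), pad=("valid", "same", "same")))
    st, c = stage(c, w5, n5)
    layers += st
    # the (2,7,7) window covers the whole remaining extent at nominal input,
    # so the printed stride difference between the variants is immaterial
    layers.append(GlobalAvgPool())
    layers.append(Linear(c, cfg.num_classes))

    body = Sequential(layers)
    body.initialize(np.random.default_rng(seed))
    return Network(cfg, body)


def count_parameters(net) -> int:
    """Exact count of trainable scalars (convs, norms, linear head)."""
    params = net.params() if hasattr(net, "params") else net
    return int(sum(p.value.size for p in params))


def parameter_increase_pct(baseline_count: float, proposed_count: float) -> float:
    """Relative parameter growth of the deeper variant, percent (1 decimal)."""
    from ..evalmetrics import round_half_up

    return round_half_up(100.0 * (proposed_count - baseline_count)
                         / baseline_count, 1)


def save_checkpoint(net: Network, path: str) -> None:
    """NPZ weight archive plus a JSON sidecar with the config and count."""
    import dataclasses
    import json

    from .layers import BatchNorm3d

    arrays = {f"p{i:04d}": p.value for i, p in enumerate(net.params())}
    bns = [l for l in net.body.iter_layers() if isinstance(l, BatchNorm3d)]
    for i, bn in enumerate(bns):
        arrays[f"bn{i:04d}_mean"] = bn.running_mean
        arrays[f"bn{i:04d}_var"] = bn.running_var
    np.savez_compressed(path, **arrays)
    sidecar = dataclasses.asdict(net.cfg)
    sidecar["channel_schedule"] = {
        "conv1": net.cfg.channel_schedule["conv1"],
        "stages": list(net.cfg.channel_schedule["stages"]),
    }
    sidecar["parameter_count"] = count_parameters(net)
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path: str) -> Network:
    import json

    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    n_params = sidecar.pop("parameter_count")
    sidecar["channel_schedule"]["stages"] = tuple(
        sidecar["channel_schedule"]["stages"])
    from .layers import BatchNorm3d

    net = build_network(NetworkConfig(**sidecar))
    with np.load(path) as z:
        for i, p in enumerate(net.params()):
            p.value = z[f"p{i:04d}"].astype(np.float32)
        bns = [l for l in net.body.iter_layers() if isinstance(l, BatchNorm3d)]
        for i, bn in enumerate(bns):
            bn.running_mean = z[f"bn{i:04d}_mean"].astype(np.float32)
            bn.running_var = z[f"bn{i:04d}_var"].astype(np.float32)
    assert count_parameters(net) == n_params
    return net
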
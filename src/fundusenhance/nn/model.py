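"""The attention-over-operations encoder-decoder network.

The model is a U-Net-style image-to-image CNN whose building block,
:class:`AttOpBlk`, applies five parallel operations to its input
feature map — 1x1, 3x3, 5x5 and 7x7 convolutions and a 3x3 stride-1
max pool, all preserving spatial size and channel count — and fuses
them adaptively. A channel-attention head computes the per-channel
spatial average of the input, maps it through a 3-layer MLP with a
final ReLU, and softmax-normalizes the five resulting logits into a
probability vector over the operations. The weighted sum of the five
branch outputs is concatenated with the block input (a residual-style
path that keeps gradients flowing to the input) and reduced by a 1x1
convolution.

The encoder stacks four such blocks, each followed by a stride-2
convolution that halves the spatial size and doubles the channel
count; a 320x320x3 input therefore reaches a 20x20x1024 latent
representation at full scale. The decoder mirrors this with 3x3
transposed convolutions, concatenating the matching encoder level's
features (U-Net skip) before each decoder block, and a final 3x3
convolution maps back to 3 channels, so output and input shapes are
identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Conv2d, ConvTranspose2d, Linear, Module

__all__ = [
    "ModelConfig",
    "AttentionTrace",
    "AttOpBlk",
    "AttentionOperationUNet",
    "build_model",
    "make_near_identity",
    "save_model",
    "load_model",
]

N_OPERATIONS = 5  # {1x1 conv, 3x3 conv, 5x5 conv, 7x7 conv, 3x3 max pool}


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the width after the stem; each of the
    ``n_levels`` encoder levels doubles it, so the latent width is
    ``base_channels * 2**n_levels`` (1024 at the full-scale default).
    ``attention_layers`` selects the 3-layer MLP attention head or the
    single-matrix variant.
    """

    n_levels: int = 4
    base_channels: int = 64
    patch_size: int = 320
    attention_layers: int = 3
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.base_channels < 1:
            raise ValueError("n_levels and base_channels must be positive")
        if self.patch_size % (2**self.n_levels) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 2^{self.n_levels}")
        if self.attention_layers not in (1, 3):
            raise ValueError("attention_layers must be 1 or 3")

    @property
    def channels(self) -> list[int]:
        """Per-level widths, stem through latent."""
        return [self.base_channels * 2**l for l in range(self.n_levels + 1)]

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    @classmethod
    def paper_full(cls) -> "ModelConfig":
        return cls(n_levels=4, base_channels=64, patch_size=320)

    @classmethod
    def desk_small(cls) -> "ModelConfig":
        """Reduced preset for CPU-scale experiments and tests."""
        return cls(n_levels=4, base_channels=8, patch_size=64)


@dataclasses.dataclass
class AttentionTrace:
    """Attention internals of one block forward, for inspection."""

    block: str
    channel_means: np.ndarray  # (N, C) per-channel spatial averages
    logits: np.ndarray         # (N, 5) post-ReLU attention logits
    weights: np.ndarray        # (N, 5) softmax-normalized weights


class AttOpBlk(Module):
    """Attention-over-operations block; see module docstring."""

    def __init__(self, rng, in_channels: int, out_channels: int,
                 attention_layers: int = 3, dtype=np.float32, name: str = "attop"):
        self.name = name
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ops = [
            Conv2d(rng, in_channels, in_channels, k, dtype=dtype) for k in (1, 3, 5, 7)
        ]
        if attention_layers == 3:
            self.mlp = [
                Linear(rng, in_channels, in_channels, dtype=dtype),
                Linear(rng, in_channels, in_channels, dtype=dtype),
                Linear(rng, in_channels, N_OPERATIONS, dtype=dtype),
            ]
        else:
            self.mlp = [Linear(rng, in_channels, N_OPERATIONS, dtype=dtype)]
        self.fusion = Conv2d(rng, 2 * in_channels, out_channels, 1, dtype=dtype)

    def attention(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """(channel means, ReLU logits, softmax weights) for input ``x``."""
        c = ag.spatial_mean(x)
        h = c
        for layer in self.mlp[:-1]:
            h = ag.relu(layer(h))
        logits = ag.relu(self.mlp[-1](h))
        weights = ag.softmax(logits, axis=-1)
        return c, logits, weights

    def __call__(self, x: Tensor, attention_override: np.ndarray | None = None
                 ) -> tuple[Tensor, AttentionTrace]:
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"{self.name}: expected {self.in_channels} channels, got {x.data.shape[1]}")
        c, logits, weights = self.attention(x)
        if attention_override is not None:
            ov = np.broadcast_to(
                np.asarray(attention_override, dtype=x.data.dtype),
                (x.data.shape[0], N_OPERATIONS)).copy()
            weights = Tensor(ov)
        branches = [op(x) for op in self.ops] + [ag.maxpool2d_3x3(x)]
        n = x.data.shape[0]
        g = None
        for i, y in enumerate(branches):
            a_i = ag.reshape(ag.getitem(weights, (slice(None), slice(i, i + 1))), (n, 1, 1, 1))
            z = ag.mul(y, a_i)
            g = z if g is None else ag.add(g, z)
        s = self.fusion(ag.concat([g, x], axis=1))
        trace = AttentionTrace(self.name, c.data.copy(), logits.data.copy(),
                               weights.data.copy())
        return s, trace


class AttentionOperationUNet(Module):
    """Full encoder-decoder model; see module docstring for the layout."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dt = config.np_dtype
        cs = config.channels
        al = config.attention_layers
        self.stem = Conv2d(rng, 3, cs[0], 3, dtype=dt)
        self.enc_att = [
            AttOpBlk(rng, cs[l], cs[l], al, dt, name=f"enc{l}") for l in range(config.n_levels)
        ]
        self.down = [
            Conv2d(rng, cs[l], cs[l + 1], 3, stride=2, dtype=dt)
            for l in range(config.n_levels)
        ]
        self.up = [
            ConvTranspose2d(rng, cs[l + 1], cs[l], dtype=dt)
            for l in reversed(range(config.n_levels))
        ]
        self.merge = [  # reduce (upsampled + skip) concat back to the level width
            Conv2d(rng, 2 * cs[l], cs[l], 1, dtype=dt)
            for l in reversed(range(config.n_levels))
        ]
        self.dec_att = [
            AttOpBlk(rng, cs[l], cs[l], al, dt, name=f"dec{l}")
            for l in reversed(range(config.n_levels))
        ]
        self.head = Conv2d(rng, cs[0], 3, 3, dtype=dt)

    def forward(self, x: Tensor | np.ndarray, return_latent: bool = False,
                attention_override: np.ndarray | None = None):
        """Run the network on an NCHW batch.

        Returns ``(output, traces)`` or ``(output, traces, latent)``
        when ``return_latent`` is set; traces list the attention state
        of every block in execution order.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.config.np_dtype))
        if x.data.ndim != 4 or x.data.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.data.shape}")
        traces: list[AttentionTrace] = []
        h = self.stem(x)
        skips: list[Tensor] = []
        for att, down in zip(self.enc_att, self.down):
            h, trace = att(h, attention_override)
            traces.append(trace)
            skips.append(h)
            h = down(h)
        latent = h
        for up, merge, att, skip in zip(self.up, self.merge, self.dec_att, reversed(skips)):
            h = up(h)
            h = merge(ag.concat([h, skip], axis=1))
            h, trace = att(h, attention_override)
            traces.append(trace)
        out = self.head(h)
        if return_latent:
            return out, traces, latent
        return out, traces

    def __call__(self, x, **kw):
        return self.forward(x, **kw)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


def build_model(config: ModelConfig, seed: int = 0) -> AttentionOperationUNet:
    """Deterministically initialized model from a config and seed."""
    return AttentionOperationUNet(config, seed)


def make_near_identity(model: AttentionOperationUNet) -> AttentionOperationUNet:
    """Rewire a model so its output equals its input (sanity preset).

    Sets the stem to embed RGB into the first three feature channels,
    every block's fusion to pass its input half through, the last
    decoder merge to select the skip path, and the head to read the
    three embedded channels back out. Useful as an untrained baseline:
    the enhancement map starts at the identity.
    """
    def passthrough(conv: Conv2d, src_offset: int, n: int):
        conv.w.data[...] = 0.0
        conv.b.data[...] = 0.0
        k = conv.kernel_size // 2
        for o in range(min(n, conv.out_channels)):
            conv.w.data[o, src_offset + o, k, k] = 1.0

    cs = model.config.channels
    passthrough(model.stem, 0, 3)
    for blk in model.enc_att + model.dec_att:
        # fusion input is concat(G, X); select the X half
        passthrough(blk.fusion, blk.in_channels, blk.out_channels)
    for merge in model.merge:
        # merge input is concat(upsampled, skip); select the skip half
        passthrough(merge, merge.out_channels, merge.out_channels)
    passthrough(model.head, 0, 3)
    return model


def save_model(model: AttentionOperationUNet, path: str | Path) -> None:
    """Checkpoint weights and config to an ``.npz`` archive."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> AttentionOperationUNet:
    with np.load(path) as archive:
        cfg = ModelConfig(**json.loads(bytes(archive["config_json"]).decode()))
        model = AttentionOperationUNet(cfg, seed=0)
        params = model.parameters()
        for i, p in enumerate(params):
            stored = archive[f"p{i}"]
            if stored.shape != p.data.shape:
                raise ValueError("checkpoint does not match model architecture")
            p.data = stored.astype(cfg.np_dtype)
    return model
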
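"""Configurable U-Net style encoder–decoder segmentation network.

The network maps an ``H x W x 3`` image to an ``H x W`` probability map of
the same size: a contracting path of conv + ReLU stacks with 2x2 max
pooling, a bottleneck stack, and an expanding path of 2x2 transposed
convolutions with skip concatenations, finished by a 1x1 sigmoid head.

Two presets are provided: ``full_config`` follows the canonical realization
of a VGG16-initializable encoder (five blocks of 64/128/256/512/512
channels with 2/2/3/3/3 convolutions, mirrored decoder, 384x384 input), and
``tiny_config`` is a first-class desk-scale variant (three blocks, base 8
channels, 96x96) small enough that the full training machinery runs in
seconds on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn import DTYPE, Adam, Conv2d, MaxPool2, ReLU, UpConv2, he_init

__all__ = [
    "UNetConfig",
    "UNet",
    "build_model",
    "tiny_config",
    "full_config",
    "load_encoder_weights",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 5
    base_channels: int = 64
    channel_schedule: Optional[tuple] = None
    convs_per_block: Optional[tuple] = None
    bottleneck_channels: Optional[int] = None
    input_size: int = 384
    use_pretrained_encoder: bool = False

    def resolved_channels(self) -> tuple:
        if self.channel_schedule is not None:
            if len(self.channel_schedule) != self.depth:
                raise ValueError("channel_schedule length must equal depth")
            return tuple(int(c) for c in self.channel_schedule)
        return tuple(min(self.base_channels * 2 ** i, self.base_channels * 8) for i in range(self.depth))

    def resolved_convs(self) -> tuple:
        if self.convs_per_block is not None:
            if len(self.convs_per_block) != self.depth:
                raise ValueError("convs_per_block length must equal depth")
            return tuple(int(c) for c in self.convs_per_block)
        if self.depth == 5:
            return (2, 2, 3, 3, 3)  # VGG16-compatible stacking
        return tuple(2 for _ in range(self.depth))

    def resolved_bottleneck(self) -> int:
        if self.bottleneck_channels is not None:
            return int(self.bottleneck_channels)
        return self.resolved_channels()[-1]

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2 ** self.depth}"
            )
        self.resolved_channels()
        self.resolved_convs()


def tiny_config() -> UNetConfig:
    """Desk-scale preset: < 200k parameters, millisecond forward passes."""
    return UNetConfig(
        depth=3,
        base_channels=8,
        channel_schedule=(8, 16, 32),
        convs_per_block=(2, 2, 2),
        bottleneck_channels=64,
        input_size=96,
    )


def full_config() -> UNetConfig:
    """Full-size preset with a VGG16-shaped five-block encoder."""
    return UNetConfig(
        depth=5,
        base_channels=64,
        channel_schedule=(64, 128, 256, 512, 512),
        convs_per_block=(2, 2, 3, 3, 3),
        input_size=384,
    )


class UNet:
    """Encoder–decoder network with explicit forward/backward passes."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        channels = cfg.resolved_channels()
        convs = cfg.resolved_convs()
        bott = cfg.resolved_bottleneck()

        self.enc_blocks = []  # list of [Conv2d, ReLU, Conv2d, ReLU, ...]
        c_prev = 3
        for i in range(cfg.depth):
            block = []
            for j in range(convs[i]):
                block.append(Conv2d(c_prev if j == 0 else channels[i], channels[i], rng))
                block.append(ReLU())
            c_prev = channels[i]
            self.enc_blocks.append(block)
        self.pools = [MaxPool2() for _ in range(cfg.depth)]
        self.bottleneck = [Conv2d(c_prev, bott, rng), ReLU()]

        self.ups = []
        self.dec_blocks = []
        c_prev = bott
        for i in reversed(range(cfg.depth)):
            self.ups.append(UpConv2(c_prev, channels[i], rng))
            block = []
            for j in range(convs[i]):
                block.append(Conv2d(2 * channels[i] if j == 0 else channels[i], channels[i], rng))
                block.append(ReLU())
            self.dec_blocks.append(block)
            c_prev = channels[i]
        self.head = Conv2d(c_prev, 1, rng, kernel=1)

    # -- parameter plumbing -------------------------------------------
    def _layers(self) -> list:
        layers = []
        for block in self.enc_blocks:
            layers.extend(block)
        layers.extend(self.bottleneck)
        for up, block in zip(self.ups, self.dec_blocks):
            layers.append(up)
            layers.extend(block)
        layers.append(self.head)
        return layers

    def encoder_convs(self) -> list:
        """Encoder Conv2d layers in order (for weight transplants)."""
        return [l for block in self.enc_blocks for l in block if isinstance(l, Conv2d)]

    def params(self) -> list:
        return [p for l in self._layers() for p in l.params()]

    def grads(self) -> list:
        return [g for l in self._layers() for g in l.grads()]

    @property
    def num_params(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Input (N, 3, H, W) float32 -> logits (N, H, W)."""
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, h, w = x.shape
        if h % (2 ** self.cfg.depth) or w % (2 ** self.cfg.depth):
            raise ValueError(f"input {h}x{w} not divisible by 2^depth={2 ** self.cfg.depth}")
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            for layer in block:
                x = layer.forward(x, train)
        logits = self.head.forward(x, train)
        return logits[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits), filling all layer gradients."""
        dx = self.head.backward(dlogits[:, None].astype(DTYPE))
        channels = self.cfg.resolved_channels()
        # decoder ran deepest-to-shallowest in forward; walk it back
        # shallowest-first, collecting skip gradients per encoder level
        dskips = []  # level 0 (shallowest) first
        for up, block, c_skip in zip(
            reversed(self.ups), reversed(self.dec_blocks), channels
        ):
            for layer in reversed(block):
                dx = layer.backward(dx)
            dskip, dup = dx[:, :c_skip], dx[:, c_skip:]
            dskips.append(np.ascontiguousarray(dskip))
            dx = up.backward(np.ascontiguousarray(dup))
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dx = pool.backward(dx)
            dx = dx + dskip
            for layer in reversed(block):
                dx = layer.backward(dx)

    def predict_logits(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        outs = [self.forward(x[i : i + batch_size], train=False) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        cfg = dict(
            depth=self.cfg.depth,
            base_channels=self.cfg.base_channels,
            channel_schedule=list(self.cfg.resolved_channels()),
            convs_per_block=list(self.cfg.resolved_convs()),
            bottleneck_channels=self.cfg.resolved_bottleneck(),
            input_size=self.cfg.input_size,
        )
        arrays = {f"param_{i}": p for i, p in enumerate(self.params())}
        np.savez(path, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        model = cls(
            UNetConfig(
                depth=cfg["depth"],
                base_channels=cfg["base_channels"],
                channel_schedule=tuple(cfg["channel_schedule"]),
                convs_per_block=tuple(cfg["convs_per_block"]),
                bottleneck_channels=cfg["bottleneck_channels"],
                input_size=cfg["input_size"],
            )
        )
        for i, p in enumerate(model.params()):
            stored = data[f"param_{i}"]
            if stored.shape != p.shape:
                raise ValueError(f"checkpoint parameter {i} shape {stored.shape} != {p.shape}")
            p[...] = stored
        return model


def build_model(cfg: UNetConfig, seed: int = 0) -> UNet:
    return UNet(cfg, seed=seed)


#: conv shapes of the five VGG16 feature blocks, flattened in order
VGG16_CONV_CHANNELS = (
    (3, 64), (64, 64),
    (64, 128), (128, 128),
    (128, 256), (256, 256), (256, 256),
    (256, 512), (512, 512), (512, 512),
    (512, 512), (512, 512), (512, 512),
)


def load_encoder_weights(model: UNet, source: str, weights_path=None, seed: int = 0) -> UNet:
    """Replace the encoder weights of ``model`` in place.

    * ``random`` — seeded He re-initialization of the encoder convs.
    * ``checkpoint`` — load *all* weights from a saved model of identical
      architecture (``weights_path`` required).
    * ``vgg16-imagenet`` — transplant VGG16 conv weights from a local ``.npz``
      file (arrays ``conv_0_W``, ``conv_0_b``, ... in block order) into the
      encoder, leaving the decoder untouched.  This is an optional hook for
      users who already have the weights on disk; nothing is ever downloaded.
    """
    if source == "random":
        rng = np.random.default_rng(seed)
        for conv in model.encoder_convs():
            conv.W[...] = he_init(rng, conv.W.shape, conv.c_in * conv.kernel ** 2)
            conv.b[...] = 0.0
        return model
    if source == "checkpoint":
        if weights_path is None:
            raise ValueError("source='checkpoint' requires weights_path")
        loaded = UNet.load(weights_path)
        for p, q in zip(model.params(), loaded.params()):
            if p.shape != q.shape:
                raise ValueError(f"checkpoint shape mismatch: {q.shape} vs {p.shape}")
            p[...] = q
        return model
    if source == "vgg16-imagenet":
        convs = model.encoder_convs()
        expected = [ (c.c_in, c.c_out) for c in convs ]
        if model.cfg.depth != 5 or tuple(expected) != VGG16_CONV_CHANNELS:
            raise ValueError(
                "VGG16 weights require the five-block 64/128/256/512/512 encoder "
                f"with 2/2/3/3/3 convolutions; model encoder is {expected}"
            )
        if weights_path is None:
            raise ValueError(
                "source='vgg16-imagenet' requires a local weights_path (.npz); "
                "weights are never downloaded"
            )
        data = np.load(weights_path, allow_pickle=False)
        for i, conv in enumerate(convs):
            W = data[f"conv_{i}_W"]
            b = data[f"conv_{i}_b"]
            if W.shape != conv.W.shape or b.shape != conv.b.shape:
                raise ValueError(f"VGG16 conv {i}: shape {W.shape} does not match {conv.W.shape}")
            conv.W[...] = W.astype(DTYPE)
            conv.b[...] = b.astype(DTYPE)
        return model
    raise ValueError(f"unknown weight source {source!r}")
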
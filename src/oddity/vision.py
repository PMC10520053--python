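"""Shared convolutional embedder.

Both architectures see riddle frames through the same five-layer CNN: input
rescaled to 80x80, five 32-channel 5x5 valid convolutions, each followed by
batch normalisation and a rectified-linear activation, 2x2/stride-2 max
pooling after convolutions 2 and 4, and dropout (rate 0.3) after
convolutions 1, 3 and 5. The final feature map is flattened into the frame
embedding eta_k; with the default configuration the spatial trace is
80 -> 76 -> 72 -> 36 -> 32 -> 28 -> 14 -> 10, giving D = 10*10*32 = 3200.

Convolutions carry no bias (batch normalisation supplies the shift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn import BatchNorm, Conv2D, Module, Tensor
from .nn import autodiff as ad
from .riddlegen.frame import Frame

__all__ = ["VisionConfig", "preprocess", "shape_trace", "embedding_dim", "VisionModel"]


@dataclass(frozen=True)
class VisionConfig:
    input_side: int = 80
    channels: int = 32
    kernel: int = 5
    n_conv: int = 5
    pool_after: tuple = (2, 4)          # 1-based conv indices followed by 2x2/2 pooling
    dropout_after: tuple = (1, 3, 5)    # 1-based conv indices followed by dropout
    dropout_rate: float = 0.3


def preprocess(frame, side: int = 80) -> np.ndarray:
    """100x100 8-bit frame -> bilinear-rescaled float ``side x side`` grid
    with gray levels mapped to [0, 1] (default 80x80)."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale frame, got shape {pixels.shape}")
    scaled = pixels.astype(np.float32) / 255.0
    if pixels.shape != (side, side):
        scaled = resize(scaled, (side, side), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    return scaled.astype(np.float32)


def shape_trace(config: VisionConfig = VisionConfig()) -> list[int]:
    """Spatial side length after each conv/pool stage."""
    side = config.input_side
    trace = [side]
    for i in range(1, config.n_conv + 1):
        side = side - (config.kernel - 1)
        if side <= 0:
            raise ValueError(f"shape trace collapsed to {side} at conv {i}")
        trace.append(side)
        if i in config.pool_after:
            if side % 2:
                raise ValueError(f"2x2/2 pooling needs an even side, got {side} "
                                 f"after conv {i}")
            side = side // 2
            trace.append(side)
    return trace


def embedding_dim(config: VisionConfig = VisionConfig()) -> int:
    """Flattened embedding dimension D implied by the shape trace."""
    return shape_trace(config)[-1] ** 2 * config.channels


class VisionModel(Module):
    """The five-conv embedder; maps (B, side, side) grids to (B, D)."""

    def __init__(self, rng: np.random.Generator, config: VisionConfig = VisionConfig()):
        self.config = config
        self.out_dim = embedding_dim(config)
        self.convs = []
        self.bns = []
        c_in = 1
        for _ in range(config.n_conv):
            self.convs.append(Conv2D(rng, c_in, config.channels, config.kernel))
            self.bns.append(BatchNorm(config.channels))
            c_in = config.channels
        self._dropout_rng = np.random.default_rng(rng.integers(0, 2**31))

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        cfg = self.config
        if x.data.ndim == 3:
            x = ad.reshape(x, (x.data.shape[0], 1, *x.data.shape[1:]))
        if x.data.shape[2] != cfg.input_side or x.data.shape[3] != cfg.input_side:
            raise ValueError(f"vision model expects {cfg.input_side}x{cfg.input_side} "
                             f"inputs, got {x.data.shape[2:]}")
        for i in range(cfg.n_conv):
            x = self.convs[i](x)
            x = self.bns[i](x, train, fuse_relu=True)   # conv -> BN -> ReLU
            if (i + 1) in cfg.pool_after:
                x = ad.maxpool2x2(x)
            if (i + 1) in cfg.dropout_after:
                x = ad.dropout(x, cfg.dropout_rate, self._dropout_rng, train)
        return ad.reshape(x, (x.data.shape[0], self.out_dim))
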
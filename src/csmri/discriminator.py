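"""Discriminator: fully sampled vs reconstructed image classifier.

A stack of stride-2 convolutions — downsampling by stride variation, never by
max pooling — each followed by batch normalization and LeakyReLU, then global
average pooling, an affine map and a logistic output in (0, 1).  Following
common practice for this family, the first convolution omits batch
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, global_avg_pool
from .nn import BatchNorm2d, Conv2d, Linear, Module

__all__ = ["DiscriminatorConfig", "Discriminator"]


@dataclass
class DiscriminatorConfig:
    n_layers: int = 4
    base_channels: int = 32
    leaky_slope: float = 0.2
    input_size: tuple[int, int] = (64, 64)


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig | None = None,
                 in_channels: int = 1, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or DiscriminatorConfig()
        h, w = cfg.input_size
        if h % 2**cfg.n_layers or w % 2**cfg.n_layers:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2^{cfg.n_layers}")
        rng = np.random.default_rng(seed)
        self.convs = []
        self.bns = []
        c_in = in_channels
        for i in range(cfg.n_layers):
            c_out = cfg.base_channels * 2**i
            self.convs.append(Conv2d(c_in, c_out, 3, stride=2, padding=1, rng=rng))
            self.bns.append(BatchNorm2d(c_out) if i > 0 else None)
            c_in = c_out
        self.fc = Linear(c_in, 1, rng=rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """Per-image probability that the input is fully sampled."""
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        if x.ndim != 4:
            raise ValueError("expected NCHW input")
        if (x.shape[2], x.shape[3]) != tuple(self.cfg.input_size):
            raise ValueError(
                f"input size {x.shape[2]}x{x.shape[3]} does not match the "
                f"{self.cfg.input_size[0]}x{self.cfg.input_size[1]} size the "
                "discriminator was built for")
        for conv, bn in zip(self.convs, self.bns):
            x = conv(x)
            if bn is not None:
                x = bn(x)
            x = x.leaky_relu(self.cfg.leaky_slope)
        pooled = global_avg_pool(x)
        return self.fc(pooled).sigmoid().reshape(x.shape[0])
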
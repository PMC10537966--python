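"""The four-term generator loss and the discriminator loss.

The generator objective combines

    L_combine = alpha * L_iMSE + beta * L_fMSE + delta * L_VGG + L_GEN

with alpha=15, beta=0.1, delta=0.0025 by default:

* ``L_iMSE``  — half the mean squared pixel difference between the fully
  sampled image ``x_t`` and the reconstruction ``x_u``;
* ``L_fMSE``  — the same quantity on the orthonormal k-space grids ``y_t``,
  ``y_u``; under the unitary transform this equals ``L_iMSE`` identically
  (Parseval), a fact the tests assert;
* ``L_VGG``   — half the mean squared difference of perceptual features from
  an injectable extractor (the default is a fixed, seeded random convolution
  stack; any callable mapping an image batch to features can be supplied);
* ``L_GEN``   — the adversarial term ``-log D(G(x_u))``.

The discriminator minimizes ``-log D(x_t) - log(1 - D(G(x_u)))``.  All "1/2
||.||^2" terms use *means* over grid points so loss magnitudes — and hence the
printed weights — are independent of image resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import Conv2d, Module, Sequential, ReLU
from .kspace import forward_fft

__all__ = [
    "LossWeights",
    "LossBundle",
    "RandomFeatureExtractor",
    "image_mse_loss",
    "freq_mse_loss",
    "perceptual_loss",
    "adversarial_gen_loss",
    "combined_loss",
    "discriminator_loss",
    "PROB_EPS",
]

PROB_EPS = 1e-7


@dataclass
class LossWeights:
    """Weights of the combined generator loss."""

    alpha: float = 15.0
    beta: float = 0.1
    delta: float = 0.0025
    # the adversarial term carries unit weight in the combination; gamma is
    # an extension knob (gamma=0 reduces training to supervised regression)
    gamma: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.delta, self.gamma) < 0:
            raise ValueError("loss weights must be nonnegative")

    def combine(self, l_imse, l_fmse, l_vgg, l_gen):
        """The weighted combination rule applied to the four term values."""
        return (self.alpha * l_imse + self.beta * l_fmse
                + self.delta * l_vgg + self.gamma * l_gen)


@dataclass
class LossBundle:
    """All loss terms of one generator evaluation (scalar tensors)."""

    l_imse: Tensor
    l_fmse: Tensor
    l_vgg: Tensor
    l_gen: Tensor
    l_combine: Tensor

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name))
                for name in ("l_imse", "l_fmse", "l_vgg", "l_gen", "l_combine")}


def _pair(xt, xu) -> tuple[Tensor, Tensor]:
    xt, xu = as_tensor(xt), as_tensor(xu)
    if xt.shape != xu.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {xu.shape}")
    return xt, xu


def image_mse_loss(xt, xu) -> Tensor:
    """Half the mean squared pixel difference (image-domain term)."""
    xt, xu = _pair(xt, xu)
    return 0.5 * ((xt - xu) ** 2).mean()


def freq_mse_loss(xt, xu) -> Tensor:
    """Half the mean squared k-space difference (frequency-domain term).

    The forward value is computed from the orthonormal DC-centered spectra of
    both images.  For real inputs Parseval's identity makes the gradient with
    respect to ``xu`` equal to the image-domain gradient, which is what the
    backward pass uses (no complex-valued graph needed).
    """
    xt, xu = _pair(xt, xu)
    diff2 = 0.0
    npts = 0
    flat_t = xt.data.reshape(-1, *xt.shape[-2:]) if xt.ndim > 2 else xt.data[None]
    flat_u = xu.data.reshape(-1, *xu.shape[-2:]) if xu.ndim > 2 else xu.data[None]
    for a, b in zip(flat_t, flat_u):
        d = forward_fft(a) - forward_fft(b)
        diff2 += float(np.sum(d.real**2 + d.imag**2))
        npts += d.size
    value = 0.5 * diff2 / npts
    out = Tensor(value)
    if xt.requires_grad or xu.requires_grad:
        out.requires_grad = True
        out._parents = (xt, xu)
        n_total = xt.size
        def back(g):
            d = (xt.data - xu.data) / n_total
            return (g * d, -g * d)
        out._backward = back
    return out


def perceptual_loss(xt, xu, extractor: Callable) -> Tensor:
    """Half the mean squared difference of extractor features."""
    xt, xu = _pair(xt, xu)
    ft = extractor(xt)
    fu = extractor(xu)
    return 0.5 * ((as_tensor(ft) - as_tensor(fu)) ** 2).mean()


def _clamped_prob(d_out) -> Tensor:
    d = as_tensor(d_out)
    if np.any(d.data < 0) or np.any(d.data > 1):
        raise ValueError("discriminator output must lie in [0, 1]")
    return d.clip(PROB_EPS, 1.0 - PROB_EPS)


def adversarial_gen_loss(d_out) -> Tensor:
    """-log D(G(x_u)), averaged over the batch, probability epsilon-clamped."""
    return -(_clamped_prob(d_out).log().mean())


def combined_loss(xt, xu, d_out, weights: LossWeights | None = None,
                  extractor: Callable | None = None) -> LossBundle:
    """Evaluate all four generator loss terms and their weighted combination."""
    weights = weights or LossWeights()
    l_imse = image_mse_loss(xt, xu)
    l_fmse = freq_mse_loss(xt, xu)
    if extractor is None:
        l_vgg = Tensor(0.0)
    else:
        l_vgg = perceptual_loss(xt, xu, extractor)
    l_gen = adversarial_gen_loss(d_out)
    l_combine = weights.combine(l_imse, l_fmse, l_vgg, l_gen)
    return LossBundle(l_imse=l_imse, l_fmse=l_fmse, l_vgg=l_vgg,
                      l_gen=l_gen, l_combine=as_tensor(l_combine))


def discriminator_loss(d_real, d_fake) -> Tensor:
    """Binary cross entropy: -log D(x_t) - log(1 - D(G(x_u)))."""
    real = _clamped_prob(d_real)
    fake = _clamped_prob(d_fake)
    return -(real.log().mean()) - ((1.0 - fake).clip(PROB_EPS, 1.0).log().mean())


class RandomFeatureExtractor(Module):
    """Fixed, seeded random convolutional feature stack.

    A small frozen network standing behind the perceptual-loss interface:
    three stride-2 3x3 convolutions with ReLU, He-initialised from a seed and
    never trained.  It is deterministic, differentiable with respect to its
    input, and maps a single-channel (N, 1, H, W) batch to a feature tensor.
    """

    def __init__(self, channels: tuple[int, ...] = (8, 16, 16), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        layers: list[Module] = []
        c_in = 1
        for c_out in channels:
            layers.append(Conv2d(c_in, c_out, 3, stride=2, padding=1, rng=rng))
            layers.append(ReLU())
            c_in = c_out
        self.net = Sequential(*layers)
        for p in self.parameters():
            p.requires_grad = False

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        return self.net(x)
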
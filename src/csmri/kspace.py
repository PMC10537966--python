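"""Retrospective compressed-sensing acquisition simulation.

Magnitude images are mapped to DC-centered k-space by an orthonormal 2-D FFT,
undersampled with variable-density random masks, zero-filled and transformed
back.  The orthonormal convention makes the transform unitary (Parseval holds
to machine precision), so loss weights defined on the image grid carry over
unchanged to the frequency grid.

Masks are drawn by a Monte-Carlo scheme: a centered square holding ~4% of the
grid (the high-energy low frequencies) is always sampled, and the remaining
points are drawn without replacement with probability proportional to an
isotropic Gaussian centered on DC.  The draw is without replacement so the
realized sampling rate equals the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "SamplingMask",
    "forward_fft",
    "inverse_fft",
    "generate_mask",
    "undersample",
    "zero_fill_recon",
    "save_mask",
    "load_mask",
]


def _check_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def forward_fft(image: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D FFT of a magnitude image, DC component at the center."""
    arr = _check_image(image)
    return np.fft.fftshift(np.fft.fft2(arr, norm="ortho"))


def inverse_fft(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_fft`; returns the complex image."""
    arr = np.asarray(kspace)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D k-space grid, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("k-space contains non-finite values")
    return np.fft.ifft2(np.fft.ifftshift(arr), norm="ortho")


@dataclass
class SamplingMask:
    """Binary k-space sampling pattern with its generating settings."""

    pattern: np.ndarray
    target_rate: float
    center_fraction: float
    sigma_scale: float
    seed: int
    center_slices: tuple[slice, slice] = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pattern.shape

    @property
    def n_sampled(self) -> int:
        return int(self.pattern.sum())

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=bool)


def _center_square(h: int, w: int, center_fraction: float) -> tuple[slice, slice]:
    """Centered square whose area best approximates center_fraction * H * W."""
    side = int(round(np.sqrt(center_fraction * h * w)))
    side = max(1, min(side, h, w))
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return slice(r0, r0 + side), slice(c0, c0 + side)


def generate_mask(height: int, width: int, target_rate: float,
                  center_fraction: float = 0.04, sigma_scale: float = 0.25,
                  seed: int = 0) -> SamplingMask:
    """Variable-density Gaussian random mask with a fully sampled center.

    The number of sampled points equals ``round(target_rate * H * W)`` exactly
    and is deterministic in ``seed``.
    """
    if not (0.0 < target_rate <= 1.0):
        raise ValueError(f"target_rate must be in (0, 1], got {target_rate}")
    if not (0.0 <= center_fraction <= target_rate):
        raise ValueError(
            f"center_fraction ({center_fraction}) must lie in [0, target_rate]")
    n = height * width
    n_target = int(round(target_rate * n))
    rs, cs = _center_square(height, width, center_fraction)
    pattern = np.zeros((height, width), dtype=bool)
    pattern[rs, cs] = True
    n_center = int(pattern.sum())
    if n_center > n_target:
        raise ValueError(
            f"target_rate {target_rate} cannot accommodate the forced "
            f"{n_center}-point central region ({n_center / n:.3f} of the grid)")
    n_extra = n_target - n_center
    if n_extra:
        rows, cols = np.mgrid[0:height, 0:width]
        # distance from the DC bin (fftshift center)
        d2 = (rows - height // 2) ** 2.0 + (cols - width // 2) ** 2.0
        sigma = sigma_scale * min(height, width)
        density = np.exp(-d2 / (2.0 * sigma**2))
        density[pattern] = 0.0
        flat = density.ravel()
        candidates = np.flatnonzero(flat > 0)
        if candidates.size < n_extra:
            # Gaussian underflows far from DC at tiny sigma: fall back to a
            # uniform floor over the remaining points
            flat = (~pattern).ravel().astype(float)
            candidates = np.flatnonzero(flat > 0)
        probs = flat[candidates] / flat[candidates].sum()
        rng = np.random.default_rng(seed)
        chosen = rng.choice(candidates, size=n_extra, replace=False, p=probs)
        pattern.ravel()[chosen] = True
    assert int(pattern.sum()) == n_target
    return SamplingMask(pattern=pattern, target_rate=target_rate,
                        center_fraction=center_fraction,
                        sigma_scale=sigma_scale, seed=seed,
                        center_slices=(rs, cs))


def undersample(kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Retain sampled k-space points; unsampled entries become exactly zero."""
    arr = np.asarray(kspace)
    if arr.shape != mask.pattern.shape:
        raise ValueError(
            f"k-space shape {arr.shape} does not match mask {mask.pattern.shape}")
    return np.where(mask.pattern, arr, 0.0 + 0.0j)


def zero_fill_recon(image: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Magnitude zero-filled reconstruction — the degraded network input."""
    k = forward_fft(image)
    return np.abs(inverse_fft(undersample(k, mask)))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_mask(mask: SamplingMask, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("pattern", data=mask.pattern.astype(np.uint8))
        ds.attrs["target_rate"] = mask.target_rate
        ds.attrs["center_fraction"] = mask.center_fraction
        ds.attrs["sigma_scale"] = mask.sigma_scale
        ds.attrs["seed"] = mask.seed


def load_mask(path) -> SamplingMask:
    with h5py.File(path, "r") as f:
        ds = f["pattern"]
        pattern = ds[()].astype(bool)
        h, w = pattern.shape
        cf = float(ds.attrs["center_fraction"])
        return SamplingMask(
            pattern=pattern,
            target_rate=float(ds.attrs["target_rate"]),
            center_fraction=cf,
            sigma_scale=float(ds.attrs["sigma_scale"]),
            seed=int(ds.attrs["seed"]),
            center_slices=_center_square(h, w, cf),
        )
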
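"""Image-quality metrics: MSE, PSNR, SSIM and per-pixel MSE maps.

Images are assumed normalized to [0, 1] (data range 1).  SSIM follows the
standard windowed formulation: 11x11 Gaussian window with sigma 1.5,
K1 = 0.01, K2 = 0.03, averaged over the map (delegated to scikit-image).
PSNR of a numerically perfect reconstruction is reported as a capped 100 dB
flag value so reports stay serializable.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["mse", "psnr", "ssim", "mse_map", "PSNR_CAP", "aggregate_metrics"]

PSNR_CAP = 100.0


def _pair(ref, test) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def mse(ref, test) -> float:
    """Mean squared difference (evaluation metric; no 1/2 factor)."""
    ref, test = _pair(ref, test)
    return float(np.mean((ref - test) ** 2))


def mse_map(ref, test) -> np.ndarray:
    """Per-pixel squared difference; its spatial mean equals :func:`mse`."""
    ref, test = _pair(ref, test)
    return (ref - test) ** 2


def psnr(ref, test, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, capped at 100 dB for identical images."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    err = mse(ref, test)
    if err == 0.0:
        return PSNR_CAP
    return float(min(10.0 * np.log10(data_range**2 / err), PSNR_CAP))


def ssim(ref, test, data_range: float = 1.0) -> float:
    """Mean structural similarity (11x11 Gaussian window, sigma 1.5)."""
    ref, test = _pair(ref, test)
    if min(ref.shape) < 11:
        raise ValueError("SSIM needs images of at least 11x11")
    return float(structural_similarity(
        ref, test, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def aggregate_metrics(refs: np.ndarray, tests: np.ndarray,
                      data_range: float = 1.0) -> dict[str, float]:
    """Mean and sd of each metric over a stack of image pairs."""
    refs = np.asarray(refs)
    tests = np.asarray(tests)
    if refs.shape != tests.shape or refs.ndim != 3:
        raise ValueError("expected matching (N, H, W) stacks")
    rows = {
        "psnr": [psnr(r, t, data_range) for r, t in zip(refs, tests)],
        "ssim": [ssim(r, t, data_range) for r, t in zip(refs, tests)],
        "mse": [mse(r, t) for r, t in zip(refs, tests)],
    }
    out: dict[str, float] = {}
    for name, values in rows.items():
        out[f"{name}_mean"] = float(np.mean(values))
        out[f"{name}_sd"] = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return out
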
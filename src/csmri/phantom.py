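"""Synthetic brain-like phantoms, stochastic augmentation and dataset splits.

The phantom is a piecewise-constant composition of ellipses: an outer "skull"
ellipse, nested random tissue ellipses at prescribed intensity levels, and a
bright compact central blob — enough structure that zero-filled undersampled
versions show measurable aliasing/blur for reconstruction to remove.  Images
live in [0, 1] and are deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "PhantomSpec",
    "DatasetSplit",
    "make_phantom",
    "make_phantom_set",
    "augment",
    "split_dataset",
    "save_phantoms",
    "load_phantoms",
]

DEFAULT_INTENSITIES = (0.25, 0.4, 0.55, 0.7, 0.85, 0.95)
SPLIT_FRACTIONS = (0.70, 0.10, 0.20)


@dataclass
class PhantomSpec:
    size: tuple[int, int] = (64, 64)
    n_ellipses: int = 6
    intensity_levels: Sequence[float] = DEFAULT_INTENSITIES
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ellipses < 3:
            raise ValueError("a phantom needs at least 3 ellipses")
        if self.noise_std < 0:
            raise ValueError("noise_std must be nonnegative")
        if not self.intensity_levels:
            raise ValueError("intensity_levels must be nonempty")


@dataclass
class DatasetSplit:
    train_items: list
    val_items: list
    test_items: list
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS
    seed: int = 0


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom; identical for identical spec (incl. seed)."""
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    levels = list(spec.intensity_levels)
    img = np.zeros((h, w))

    # outer skull ellipse: thin bright rim around the head outline
    ry, rx = 0.46 * h, 0.40 * w
    outer = _ellipse_mask(h, w, h / 2, w / 2, ry, rx, 0.0)
    inner = _ellipse_mask(h, w, h / 2, w / 2, 0.92 * ry, 0.92 * rx, 0.0)
    rim_level = max(levels)
    brain_level = levels[0]
    img[outer] = rim_level
    img[inner] = brain_level

    # nested tissue ellipses, overwriting (piecewise-constant tissue regions)
    for k in range(spec.n_ellipses - 2):
        level = levels[(k + 1) % len(levels)]
        cy = h / 2 + rng.uniform(-0.18, 0.18) * h
        cx = w / 2 + rng.uniform(-0.18, 0.18) * w
        ery = rng.uniform(0.06, 0.22) * h
        erx = rng.uniform(0.06, 0.22) * w
        theta = rng.uniform(0, np.pi)
        img[_ellipse_mask(h, w, cy, cx, ery, erx, theta) & inner] = level

    # bright compact center (deep gray-matter-like blob)
    center = _ellipse_mask(h, w, h / 2, w / 2, 0.07 * h, 0.07 * w,
                           rng.uniform(0, np.pi))
    img[center] = rim_level

    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, img.shape)
    return np.clip(img, 0.0, 1.0)


def make_phantom_set(n: int, spec: PhantomSpec | None = None,
                     seed: int | None = None) -> np.ndarray:
    """Stack of ``n`` phantoms with per-item seeds spawned from ``seed``."""
    spec = spec or PhantomSpec()
    base = spec.seed if seed is None else seed
    seeds = np.random.SeedSequence(base).generate_state(n)
    images = [
        make_phantom(PhantomSpec(size=spec.size, n_ellipses=spec.n_ellipses,
                                 intensity_levels=spec.intensity_levels,
                                 noise_std=spec.noise_std, seed=int(s)))
        for s in seeds
    ]
    return np.stack(images)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUGMENT_NAMES = ("flip_ud", "mirror_lr", "rotate90", "translate")


def augment(image: np.ndarray, seed: int) -> np.ndarray:
    """Apply one of four transforms, chosen with equal probability.

    The transforms are vertical flip, horizontal mirror, 90-degree rotation
    and integer translation by up to 10% of each dimension (zero padding).
    Shape is preserved; rotation of non-square images falls back to two flips
    (a 180-degree rotation) to keep the grid size.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("augment expects a 2-D image")
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, 4)
    if choice == 0:
        return np.flipud(arr).copy()
    if choice == 1:
        return np.fliplr(arr).copy()
    if choice == 2:
        if arr.shape[0] == arr.shape[1]:
            return np.rot90(arr).copy()
        return np.flipud(np.fliplr(arr)).copy()
    h, w = arr.shape
    max_dy = max(1, int(round(0.10 * h)))
    max_dx = max(1, int(round(0.10 * w)))
    dy = int(rng.integers(-max_dy, max_dy + 1))
    dx = int(rng.integers(-max_dx, max_dx + 1))
    out = np.zeros_like(arr)
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = arr[src_y, src_x]
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(item_ids: Sequence, seed: int = 0) -> DatasetSplit:
    """Seeded shuffle then contiguous 70/10/20 slicing.

    Validation and test sizes are ``round(0.1 n)`` and ``round(0.2 n)``; the
    remainder goes to training.  Requires at least 10 items.
    """
    items = list(item_ids)
    n = len(items)
    if n < 10:
        raise ValueError(f"need at least 10 items to split 70/10/20, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [items[i] for i in order]
    n_val = int(round(SPLIT_FRACTIONS[1] * n))
    n_test = int(round(SPLIT_FRACTIONS[2] * n))
    n_train = n - n_val - n_test
    return DatasetSplit(
        train_items=shuffled[:n_train],
        val_items=shuffled[n_train:n_train + n_val],
        test_items=shuffled[n_train + n_val:],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_phantoms(images: np.ndarray, spec: PhantomSpec, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("images", data=np.asarray(images))
        ds.attrs["size"] = spec.size
        ds.attrs["n_ellipses"] = spec.n_ellipses
        ds.attrs["intensity_levels"] = list(spec.intensity_levels)
        ds.attrs["noise_std"] = spec.noise_std
        ds.attrs["seed"] = spec.seed


def load_phantoms(path) -> tuple[np.ndarray, PhantomSpec]:
    with h5py.File(path, "r") as f:
        ds = f["images"]
        images = ds[()]
        spec = PhantomSpec(
            size=tuple(int(v) for v in ds.attrs["size"]),
            n_ellipses=int(ds.attrs["n_ellipses"]),
            intensity_levels=tuple(float(v) for v in ds.attrs["intensity_levels"]),
            noise_std=float(ds.attrs["noise_std"]),
            seed=int(ds.attrs["seed"]),
        )
    return images, spec
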
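"""Disk formats: NIfTI slice ingestion, HDF5 checkpoints, PNG export.

Array containers on disk are HDF5 with self-describing attributes; PNG export
is 8-bit and for visualization only.  Real T1-weighted volumes can be read
slice-wise from NIfTI, each slice min-max normalized to [0, 1] (constant
slices map to zero).
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .discriminator import Discriminator, DiscriminatorConfig
from .generator import Generator, GeneratorConfig

__all__ = ["load_nifti_slices", "save_checkpoint", "load_checkpoint",
           "save_png"]

_AXIS_NAMES = {"sagittal": 0, "coronal": 1, "axial": 2}


def load_nifti_slices(path, axis: int | str = "axial",
                      normalize: bool = True) -> list[np.ndarray]:
    """Extract 2-D slices from a NIfTI volume along the chosen axis.

    Returns one slice per index along the axis, in index order.  With
    ``normalize`` each slice is min-max scaled to [0, 1]; a constant slice
    has no range and maps to all zeros.
    """
    import nibabel as nib

    try:
        vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    except Exception as exc:
        raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {vol.shape}")
    ax = _AXIS_NAMES.get(axis, axis)
    if ax not in (0, 1, 2):
        raise ValueError(f"axis must be 0/1/2 or one of {sorted(_AXIS_NAMES)}")
    slices = []
    for i in range(vol.shape[ax]):
        sl = np.take(vol, i, axis=ax)
        if normalize:
            lo, hi = sl.min(), sl.max()
            sl = (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)
        slices.append(sl)
    return slices


def _cfg_to_json(cfg) -> str:
    return json.dumps(dataclasses.asdict(cfg))


def _write_state(group: h5py.Group, state: dict[str, np.ndarray]) -> None:
    for key, value in state.items():
        group.create_dataset(key, data=value)


def save_checkpoint(path, generator: Generator,
                    discriminator: Discriminator | None = None,
                    extra: dict | None = None) -> None:
    """Serialize network parameters with their configs embedded."""
    with h5py.File(path, "w") as f:
        g = f.create_group("generator")
        g.attrs["config"] = _cfg_to_json(generator.cfg)
        _write_state(g, generator.state_dict())
        if discriminator is not None:
            d = f.create_group("discriminator")
            d.attrs["config"] = _cfg_to_json(discriminator.cfg)
            _write_state(d, discriminator.state_dict())
        if extra:
            f.attrs["extra"] = json.dumps(extra)


def load_checkpoint(path) -> tuple[Generator, Discriminator | None, dict]:
    with h5py.File(path, "r") as f:
        gcfg = json.loads(f["generator"].attrs["config"])
        gcfg["dilation_rates"] = tuple(gcfg["dilation_rates"])
        generator = Generator(GeneratorConfig(**gcfg))
        generator.load_state_dict({k: v[()] for k, v in f["generator"].items()})
        discriminator = None
        if "discriminator" in f:
            dcfg = json.loads(f["discriminator"].attrs["config"])
            dcfg["input_size"] = tuple(dcfg["input_size"])
            discriminator = Discriminator(DiscriminatorConfig(**dcfg))
            discriminator.load_state_dict(
                {k: v[()] for k, v in f["discriminator"].items()})
        extra = json.loads(f.attrs["extra"]) if "extra" in f.attrs else {}
    return generator, discriminator, extra


def save_png(path, image: np.ndarray, cmap: str = "gray") -> None:
    """8-bit PNG export of an image or heatmap (visualization only)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arr = np.asarray(image, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    norm = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    plt.imsave(str(path), norm, cmap=cmap, vmin=0.0, vmax=1.0)
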
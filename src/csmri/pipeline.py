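"""Run-level orchestration: resolved configuration, model evaluation across
sampling rates, and the ablation study harness.

A :class:`RunConfig` is the fully resolved union of all module configs plus
the output directory and global seed; it round-trips through YAML unchanged
and is written into every run directory so any run can be reproduced from its
own artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .discriminator import DiscriminatorConfig
from .generator import Generator, GeneratorConfig
from .kspace import SamplingMask, generate_mask, zero_fill_recon
from .losses import LossWeights
from .metrics import aggregate_metrics
from .training import TrainConfig, TrainResult, train, validation_mask_seed

__all__ = ["RunConfig", "evaluate_rates", "run_ablation", "ABLATION_VARIANTS",
           "mask_hash"]

ABLATION_VARIANTS = ("full", "no_dr", "no_cam", "no_fusion")


@dataclass
class RunConfig:
    """Fully resolved configuration of one training/evaluation run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    weights: LossWeights = field(default_factory=LossWeights)
    training: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str = "runs/run0"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        # tuples serialize as lists; from_yaml restores them
        return yaml.safe_dump(json.loads(json.dumps(d)), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        gen = d.get("generator", {})
        if "dilation_rates" in gen:
            gen["dilation_rates"] = tuple(gen["dilation_rates"])
        disc = d.get("discriminator", {})
        if "input_size" in disc:
            disc["input_size"] = tuple(disc["input_size"])
        return cls(
            generator=GeneratorConfig(**gen),
            discriminator=DiscriminatorConfig(**disc),
            weights=LossWeights(**d.get("weights", {})),
            training=TrainConfig(**d.get("training", {})),
            out_dir=d.get("out_dir", "runs/run0"),
            seed=int(d.get("seed", 0)),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "config.yaml"
        path.write_text(self.to_yaml())
        return path


def mask_hash(mask: SamplingMask) -> str:
    return hashlib.sha256(np.packbits(mask.pattern).tobytes()).hexdigest()[:12]


def evaluate_rates(generator: Generator, images: np.ndarray,
                   rates: list[float], seed: int = 0,
                   center_fraction: float = 0.04,
                   sigma_scale: float = 0.25) -> dict:
    """PSNR/SSIM/MSE (mean +- sd) per sampling rate, with zero-fill baseline.

    Every image gets one fixed mask per rate, derived from the seed, so the
    report is deterministic and directly comparable across models.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ValueError("expected an (N, H, W) stack")
    n, h, w = images.shape
    report: dict[str, dict] = {}
    for rate in rates:
        zf = np.empty_like(images)
        hashes = []
        for i in range(n):
            mask = generate_mask(h, w, rate, center_fraction, sigma_scale,
                                 seed=validation_mask_seed(seed, i))
            hashes.append(mask_hash(mask))
            zf[i] = zero_fill_recon(images[i], mask)
        rec = np.clip(generator.reconstruct(zf), 0.0, 1.0)
        entry = {
            "reconstruction": aggregate_metrics(images, rec),
            "zero_filled": aggregate_metrics(images, zf),
            "mask_hashes": hashes,
        }
        report[f"{rate:g}"] = entry
    return report


def _variant_generator_config(base: GeneratorConfig, variant: str) -> GeneratorConfig:
    cfg = dataclasses.replace(base)
    if variant == "no_dr":
        cfg = dataclasses.replace(cfg, use_dilation=False)
    elif variant == "no_cam":
        cfg = dataclasses.replace(cfg, use_cam=False)
    elif variant == "no_fusion":
        cfg = dataclasses.replace(cfg, use_fusion=False)
    elif variant != "full":
        raise ValueError(f"unknown ablation variant {variant!r}")
    return cfg


def run_ablation(base: RunConfig, images: np.ndarray,
                 rates: list[float] | None = None,
                 variants: tuple[str, ...] = ABLATION_VARIANTS,
                 callback=None) -> "pandas.DataFrame":
    """Train each ablation variant with identical seed/data/masks and
    tabulate SSIM, MSE and PSNR per variant per sampling rate.

    Any variant failure aborts the table; rows completed so far are attached
    to the raised error.
    """
    import pandas as pd

    rates = rates or [base.training.sampling_rate]
    rows: list[dict] = []
    results: dict[str, TrainResult] = {}
    for variant in variants:
        gen_cfg = _variant_generator_config(base.generator, variant)
        try:
            result = train(images, gen_cfg, base.discriminator, base.weights,
                           base.training, callback=callback)
        except Exception as exc:
            err = RuntimeError(f"ablation variant {variant!r} failed: {exc}")
            err.partial_rows = rows  # type: ignore[attr-defined]
            raise err from exc
        results[variant] = result
        result.generator.load_state_dict(result.best_state["generator"])
        report = evaluate_rates(result.generator, images, rates,
                                seed=base.training.seed,
                                center_fraction=base.training.center_fraction,
                                sigma_scale=base.training.sigma_scale)
        for rate_key, entry in report.items():
            rows.append({
                "sampling_rate": float(rate_key),
                "variant": variant,
                "ssim": entry["reconstruction"]["ssim_mean"],
                "mse": entry["reconstruction"]["mse_mean"],
                "psnr": entry["reconstruction"]["psnr_mean"],
                "mask_hash": hashlib.sha256(
                    "".join(entry["mask_hashes"]).encode()).hexdigest()[:12],
            })
    table = pd.DataFrame(rows).sort_values(
        ["sampling_rate", "variant"]).reset_index(drop=True)
    table.attrs["results"] = results
    return table
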
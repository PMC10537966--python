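"""Alternating GAN optimization with ADAM, step-decay schedule and
patience-based early stopping.

One alternating step = one discriminator ADAM update (on real images vs
detached reconstructions) followed by one generator update on the combined
four-term loss.  The learning rate of both optimizers decays by a factor of
0.5 every 10 epochs from 1e-4.  Training halts when the best validation MSE
has not improved for `patience` (default 20) consecutive epochs; the
parameters of the best epoch are retained.

Masks: every training sample gets a fresh Monte-Carlo mask each epoch
(maximizing the incoherence the model sees), while each validation image
keeps one fixed mask derived from the global seed, so validation metrics are
reproducible across epochs and runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .autodiff import Tensor
from .discriminator import Discriminator, DiscriminatorConfig
from .generator import Generator, GeneratorConfig
from .kspace import generate_mask, zero_fill_recon
from .losses import (LossWeights, RandomFeatureExtractor, combined_loss,
                     discriminator_loss)
from .metrics import mse, psnr, ssim
from .nn import Adam
from .phantom import augment, split_dataset

__all__ = ["TrainConfig", "TrainHistory", "TrainResult",
           "TrainingDiverged", "lr_at_epoch", "early_stop", "train"]


class TrainingDiverged(RuntimeError):
    """Raised when a non-finite loss is encountered; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    lr_decay: float = 0.5
    lr_interval: int = 10
    patience: int = 20
    batch_size: int = 16
    max_epochs: int = 50
    max_steps: int | None = None
    disc_steps: int = 1
    seed: int = 0
    sampling_rate: float = 0.2
    center_fraction: float = 0.04
    sigma_scale: float = 0.25
    use_augmentation: bool = True


@dataclass
class TrainHistory:
    """Per-epoch records: losses, validation metrics, learning rate."""

    records: list[dict] = field(default_factory=list)

    def append(self, record: dict) -> None:
        if self.records and record["epoch"] != self.records[-1]["epoch"] + 1:
            raise ValueError("epoch records must be contiguous")
        if not self.records and record["epoch"] != 0:
            raise ValueError("history must start at epoch 0")
        self.records.append(record)

    @property
    def val_mse(self) -> list[float]:
        return [r["val_mse"] for r in self.records]

    @property
    def best_epoch(self) -> int:
        if not self.records:
            raise ValueError("empty history")
        return int(np.argmin(self.val_mse))


@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator
    history: TrainHistory
    best_state: dict
    config: TrainConfig


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step-decay schedule: lr0 * decay^floor(epoch / interval)."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.lr_interval)


def early_stop(val_mse: "TrainHistory | list[float]", patience: int) -> tuple[bool, int]:
    """Patience rule on the validation-MSE sequence.

    Returns ``(stop, best_epoch)``: stop is True once the best value has not
    improved for `patience` consecutive epochs after it occurred.
    """
    seq = val_mse.val_mse if isinstance(val_mse, TrainHistory) else list(val_mse)
    if not seq:
        raise ValueError("empty history")
    best = int(np.argmin(seq))
    return (len(seq) - 1 - best) >= patience, best


def _mask_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def validation_mask_seed(global_seed: int, item: int) -> int:
    """Fixed per-image mask seed used for validation/test reconstruction."""
    return _mask_seed(global_seed, 0x5EED, item)


def train(images: np.ndarray,
          gen_cfg: GeneratorConfig | None = None,
          disc_cfg: DiscriminatorConfig | None = None,
          weights: LossWeights | None = None,
          cfg: TrainConfig | None = None,
          extractor: Callable | None = None,
          callback: Callable[[dict], None] | None = None) -> TrainResult:
    """Train the GAN on a stack of (N, H, W) ground-truth images in [0, 1].

    The dataset is split 70/10/20 internally; validation PSNR/SSIM/MSE are
    computed every epoch on fixed per-image masks.  Deterministic given
    ``cfg.seed`` under single-threaded execution.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ValueError("expected an (N, H, W) image stack")
    n, h, w = images.shape
    cfg = cfg or TrainConfig()
    weights = weights or LossWeights()
    gen_cfg = gen_cfg or GeneratorConfig()
    if disc_cfg is None:
        disc_cfg = DiscriminatorConfig(input_size=(h, w))

    split = split_dataset(list(range(n)), seed=cfg.seed)
    generator = Generator(gen_cfg, seed=cfg.seed)
    discriminator = Discriminator(disc_cfg, seed=cfg.seed + 1)
    if extractor is None and weights.delta > 0:
        extractor = RandomFeatureExtractor(seed=cfg.seed)

    opt_g = Adam(generator.parameters(), lr=cfg.lr0,
                 betas=(cfg.adam_beta1, cfg.adam_beta2))
    opt_d = Adam(discriminator.parameters(), lr=cfg.lr0,
                 betas=(cfg.adam_beta1, cfg.adam_beta2))

    val_masks = {
        item: generate_mask(h, w, cfg.sampling_rate, cfg.center_fraction,
                            cfg.sigma_scale,
                            seed=validation_mask_seed(cfg.seed, item))
        for item in split.val_items
    }

    history = TrainHistory()
    best_state: dict = {}
    best_mse = np.inf
    global_step = 0
    epoch_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0xA11]))

    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(cfg, epoch)
        opt_g.lr = lr
        opt_d.lr = lr
        generator.train()
        discriminator.train()

        order = epoch_rng.permutation(len(split.train_items))
        epoch_losses: list[dict[str, float]] = []
        stop_steps = False
        for start in range(0, len(order), cfg.batch_size):
            if cfg.max_steps is not None and global_step >= cfg.max_steps:
                stop_steps = True
                break
            batch_items = [split.train_items[i] for i in order[start:start + cfg.batch_size]]
            xt = np.empty((len(batch_items), 1, h, w))
            xu = np.empty_like(xt)
            for j, item in enumerate(batch_items):
                img = images[item]
                if cfg.use_augmentation:
                    img = augment(img, seed=_mask_seed(cfg.seed, epoch, item, 1))
                mask = generate_mask(h, w, cfg.sampling_rate,
                                     cfg.center_fraction, cfg.sigma_scale,
                                     seed=_mask_seed(cfg.seed, epoch, item, 2))
                xt[j, 0] = img
                xu[j, 0] = zero_fill_recon(img, mask)

            xt_t = Tensor(xt)
            xu_rec = generator(Tensor(xu))

            # discriminator update(s) on detached reconstructions
            d_loss_val = np.nan
            for _ in range(cfg.disc_steps):
                opt_d.zero_grad()
                d_real = discriminator(xt_t)
                d_fake = discriminator(xu_rec.detach())
                d_loss = discriminator_loss(d_real, d_fake)
                d_loss_val = float(d_loss)
                d_loss.backward()
                opt_d.step()

            # generator update on the combined loss
            opt_g.zero_grad()
            opt_d.zero_grad()  # discard cross-gradients from the G step
            d_out = discriminator(xu_rec)
            bundle = combined_loss(xt_t, xu_rec, d_out, weights, extractor)
            losses = bundle.to_dict()
            losses["l_disc"] = d_loss_val
            if not all(np.isfinite(v) for v in losses.values()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {global_step}",
                    diagnostics={"epoch": epoch, "step": global_step,
                                 "losses": losses, "lr": lr})
            bundle.l_combine.backward()
            opt_g.step()
            opt_d.zero_grad()
            epoch_losses.append(losses)
            global_step += 1

        generator.eval()
        discriminator.eval()
        val_metrics = _validate(generator, images, split.val_items, val_masks)
        record = {
            "epoch": epoch,
            "lr": lr,
            "steps": global_step,
            **{k: float(np.mean([d[k] for d in epoch_losses])) if epoch_losses
               else np.nan
               for k in ("l_imse", "l_fmse", "l_vgg", "l_gen", "l_combine",
                         "l_disc")},
            **val_metrics,
        }
        history.append(record)
        if callback is not None:
            callback(record)

        if record["val_mse"] < best_mse:
            best_mse = record["val_mse"]
            best_state = {
                "generator": generator.state_dict(),
                "discriminator": discriminator.state_dict(),
                "epoch": epoch,
            }
        stop, _ = early_stop(history, cfg.patience)
        if stop or stop_steps:
            break

    return TrainResult(generator=generator, discriminator=discriminator,
                       history=history, best_state=best_state, config=cfg)


def _validate(generator: Generator, images: np.ndarray, items: list[int],
              masks: dict) -> dict[str, float]:
    psnrs, ssims, mses, zf_psnrs = [], [], [], []
    for item in items:
        truth = images[item]
        zf = zero_fill_recon(truth, masks[item])
        rec = np.clip(generator.reconstruct(zf[None])[0], 0.0, 1.0)
        psnrs.append(psnr(truth, rec))
        ssims.append(ssim(truth, rec))
        mses.append(mse(truth, rec))
        zf_psnrs.append(psnr(truth, zf))
    return {
        "val_psnr": float(np.mean(psnrs)),
        "val_ssim": float(np.mean(ssims)),
        "val_mse": float(np.mean(mses)),
        "val_zf_psnr": float(np.mean(zf_psnrs)),
    }
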
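# csmri

Compressed-sensing MRI (CS-MRI) reconstruction with a GAN whose generator is
a U-net augmented by **dilated residual (DR) blocks**, a **channel attention
mechanism (CAM)** and **multi-scale information fusion** — for researchers
who want a fully inspectable, CPU-runnable implementation of this family of
reconstruction models, exercisable end-to-end on synthetic brain-like
phantoms (no scanner data or GPU required).

## The problem and the model

MRI acquires data in k-space (the 2-D spatial-frequency domain). Sampling
below the Nyquist rate shortens scans but, after zero-filling the missing
k-space points and inverse Fourier transforming, yields aliased, blurred
images. This package simulates that acquisition and trains a generator
G<sub>θg</sub> to map the zero-filled image *x*<sub>u</sub> back to the fully
sampled image *x*<sub>t</sub>, while a discriminator D<sub>θd</sub> learns to
tell reconstructions from fully sampled images.

Undersampling uses Monte-Carlo variable-density masks: the central 4% of
k-space (a centered square) is always sampled, and the remaining points are
drawn without replacement with probability proportional to a Gaussian
density centered on DC, so the realized rate equals the target exactly.

The generator minimizes the weighted four-term objective

```
L_combine = α·L_iMSE + β·L_fMSE + δ·L_VGG + L_GEN,     α=15, β=0.1, δ=0.0025
```

where `L_iMSE = ½‖x_t − x_u‖²` (mean over pixels), `L_fMSE = ½‖y_t − y_u‖²`
on the orthonormal k-space grids, `L_VGG` is a perceptual feature-space MSE
through an injectable extractor, and `L_GEN = −log D(G(x_u))`. The
discriminator minimizes `−log D(x_t) − log(1 − D(G(x_u)))`. Optimization is
alternating ADAM (β₁=0.9, β₂=0.999, lr 10⁻⁴ halved every 10 epochs) with
patience-20 early stopping on validation MSE. Networks are implemented on a
small float64 reverse-mode autodiff engine included in the package, so every
layer and gradient is plain numpy.

## Worked example

```python
from csmri import (make_phantom_set, PhantomSpec, train, TrainConfig,
                   GeneratorConfig, DiscriminatorConfig)

images = make_phantom_set(120, PhantomSpec(size=(64, 64), noise_std=0.01),
                          seed=7)
result = train(
    images,
    GeneratorConfig(depth=3, base_channels=8),
    DiscriminatorConfig(n_layers=3, base_channels=8, input_size=(64, 64)),
    None,  # default loss weights α=15, β=0.1, δ=0.0025
    TrainConfig(batch_size=4, max_steps=300, max_epochs=100, seed=1,
                sampling_rate=0.2),
)
last = result.history.records[-1]
print(f"zero-filled {last['val_zf_psnr']:.2f} dB -> "
      f"reconstruction {last['val_psnr']:.2f} dB")
```

prints (about two minutes on one CPU core):

```
zero-filled 16.48 dB -> reconstruction 17.87 dB
```

i.e. after 300 alternating steps at a 20% sampling rate the reconstruction
of held-out phantoms is already 1.4 dB above the zero-filled baseline it
started from; longer training continues to widen the gap.

The same workflow is available from the shell:

```
csmri make-phantoms --n 120 --size 64 --seed 7 --out phantoms.h5
csmri make-masks --height 64 --width 64 --rate 0.2 --seed 1 --out masks/
csmri train --data phantoms.h5 --out run/ --seed 1
csmri evaluate --checkpoint run/checkpoint.h5 --data phantoms.h5 \
               --rates 0.1,0.2,0.3,0.5 --out report.json
csmri ablate --data phantoms.h5 --out ablation/   # full / no-DR / no-CAM / no-fusion
```

Every run directory contains the resolved YAML config and a JSONL log with
the seed and config hash, so runs are repeatable from their own artifacts.

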
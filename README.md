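# joshua-seg

Semantic segmentation and physical quantification of adipose tissue in
histology images, built around UNET variants whose skip connections carry
**learnable spatial histogram features** (statistical texture), with both
concatenation and attention-inspired elementwise fusion.

## The problem

When biomaterial scaffolds (e.g. silk fibroin sponges) are implanted into
soft tissue, the amount of fat that accumulates in and around the implant is
a key design readout. In H&E-stained sections adipocytes appear as white
rounded regions with thin stained membranes — easy for a human to point at,
tedious and bias-prone to annotate at scale, and easy for a plain
classifier to confuse with the scaffold's own spherical pores. This package
segments adipose pixels with encoder-decoder networks, converts the
predicted masks into areas in µm², and aggregates them by time point and
biomaterial condition.

## The model

The core block is a differentiable histogram layer placed on each
"copy-and-crop" skip connection of a UNET. Given D encoder feature maps, a
learned 1×1 convolution reduces them to K channels; each reduced value x is
softly assigned to B bins through Gaussian radial-basis responses with
learnable centers μ_bk and widths γ_bk, and the assignments are averaged
over a local S×T window:

    H_rcbk = (1 / ST) · Σ_s Σ_t exp( −γ²_bk · (x_{r+s, c+t, k} − μ_bk)² )

With B·K = D the block conserves the channel count, so its output can be
fused into the decoder wherever the raw skip features could. Five network
variants are built from one declarative spec:

| variant          | skip transform  | fusion         |
|------------------|-----------------|----------------|
| `unet`           | identity        | concatenation  |
| `unet_plus`      | identity        | elementwise ×  |
| `attention_unet` | additive gate   | concatenation  |
| `joshua`         | histogram block | concatenation  |
| `joshua_plus`    | histogram block | elementwise ×  |

Elementwise (Hadamard) fusion acts as a constrained attention mechanism —
the histogram responses in (0, 1] weight the decoder features — and halves
every decoder input width, which removes ≈18% of the learnable parameters.

The networks run on a compact numpy reverse-mode autodiff engine that ships
with the package (`joshua_seg.nn`); everything is CPU, float64 and
bit-deterministic under a seed.

## Worked example

```python
import numpy as np
from joshua_seg import (ModelSpec, HistogramBlockConfig, SyntheticSpec,
                        TrainConfig, build_model, count_parameters,
                        render_synthetic_pair, train_one)
from joshua_seg.quantify import adipose_area
from joshua_seg.training import predict_probs

hist = HistogramBlockConfig(input_channels=64, bins=16, reduced_channels=4)
for variant in ("unet", "unet_plus", "joshua", "joshua_plus"):
    spec = ModelSpec(variant, histogram=hist if "joshua" in variant else None)
    print(f"{variant:12s} {count_parameters(build_model(spec, 0)):>10,d} parameters")

synth = SyntheticSpec(n_images=32, height=64, width=64, seed=42)
rng = np.random.default_rng(synth.seed)
pairs = [render_synthetic_pair(synth, rng) for _ in range(synth.n_images)]
spec = ModelSpec("joshua_plus", depth=2, base_channels=8,
                 histogram=HistogramBlockConfig(8, 4, 2))
model = build_model(spec, seed=0)
record = train_one(model, pairs[:24], pairs[24:],
                   TrainConfig(epochs=20, patience=5, repeats_per_epoch=1,
                               batch_size=8), seed=0)
print(f"stopped at epoch {record.stopped_epoch}, "
      f"validation dice {record.metrics['dice']:.3f}, "
      f"recall {record.metrics['recall']:.3f}")

image, truth = pairs[-1]
mask = (predict_probs(model, image) >= 0.5).astype(np.uint8)
area = adipose_area(mask, ia_full=64 * 64, rl=synth.reference_length)
print(f"predicted adipose area: {area.fa_full:.1f} um^2 "
      f"(truth {adipose_area(truth, 64 * 64, synth.reference_length).fa_full:.1f})")
```

prints

```
unet         17,258,561 parameters
unet_plus    14,125,121 parameters
joshua       17,282,241 parameters
joshua_plus  14,148,801 parameters
stopped at epoch 20, validation dice 0.881, recall 0.891
predicted adipose area: 217.2 um^2 (truth 209.2)
```

The parameter table shows the ≈18% reduction of the multiply-fusion
variants (17.26M → 14.13M, 17.28M → 14.15M). The tiny desk-scale network
(depth 2, 8 base channels, 4 histogram bins) learns the synthetic adipocyte
task to dice 0.88 in 20 CPU epochs, and the predicted physical area on a
held-out image is within a few percent of the generator's ground truth.

A command-line interface mirrors this workflow on directories of images:

```bash
joshua synth --seed 0 --out data/          # synthetic dataset + manifest
joshua train --config cfg.yaml --manifest data/manifest.csv --out run/
joshua segment --checkpoint run/model.ckpt.npz --source data/manifest.csv --out seg/
joshua quantify --areas seg/areas.csv --by week --out weekly.csv
```

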
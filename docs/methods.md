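# Methods

## Model

All five networks share one encoder-decoder skeleton. The encoder is the
classic double-convolution stack: two 3×3 convolutions with ReLU per level,
2×2 max pooling between levels, channel width doubling from `base_channels`
(default 64) over `depth` (default 4) down-steps. The deepest block keeps
the width of the last skip level rather than doubling again — with bilinear
2× upsampling (no transposed convolutions) this makes the upsampled decoder
map at every level carry exactly the channel count of the same-level skip,
which elementwise fusion requires. Decoder blocks are
`DoubleConv(fused → mid → out)` with the intermediate width equal to the
skip width; a 1×1 convolution and a sigmoid produce the per-pixel
probability of the positive class, thresholded at 0.5 with ties going to
the positive class. Batch normalization is not used anywhere.

Under this accounting the concatenation baseline has 17,258,561 trainable
parameters and the elementwise variant 14,125,121 — an 18.2% reduction
(18.1% for the histogram pair). The reduction comes entirely from the
halved decoder input widths.

### Histogram block

The histogram block computes local statistical texture features. A 1×1
convolution (no bias, no nonlinearity — it is purely a dimension reducer)
maps D skip channels to K; each reduced value is softly binned by
`exp(−γ²(x − μ)²)` with learnable centers μ and widths γ (one pair per bin
per reduced channel), and responses are averaged over a sliding S×T window
(default 2×2). Output channels are ordered bin-major within each reduced
channel (channel *k* occupies slots `k·B … k·B+B−1`); with B·K = D enforced
at construction, the block conserves the channel count.

Numerical choices:

- **Spatial handling.** The window average runs at stride 1 over a
  replicate-padded map (pad bottom/right by S−1, T−1, matching the
  one-sided window indexing of the defining sum), so the output spatial
  size equals the input's and fusion needs no cropping. A `pool` mode
  (stride = window, bilinear resize back) is provided for parity
  experiments; `preserve` is the default.
- **Initialization.** Centers are linearly spaced on [−2, 2] per channel —
  a symmetric span covering typical normalized activations; widths start at
  the constant B/4 so adjacent bins overlap moderately. Both are learned by
  backpropagation (gradients validated against central finite differences
  to < 1e−3 relative error).
- **Width parameterization.** γ is stored unconstrained and squared inside
  the response, so no positivity constraint is needed and the layer is
  exactly invariant to the sign of any width entry.
- The response lies in (0, 1] in exact arithmetic; the exponential may
  underflow to 0.0 in float64 for extreme width×offset products.

### Attention gate (comparison model)

The additive attention gate projects encoder and (upsampled) decoder maps
to an intermediate width of half the encoder channels with 1×1
convolutions, sums, applies ReLU, maps to one channel, and squashes with a
sigmoid; the coefficients multiply the encoder map before concatenation.

## Training protocol

Weighted binary cross entropy,
`−mean[w·y·log p + (1−y)·log(1−p)]`, with the weight `w` (default 3,
against the heavy background/adipose imbalance) applied to the positive
term only; probabilities are clamped to [1e−7, 1−1e−7] before the logs.
Adam at learning rate 1e−3 with weight decay 1e−8 (L2 added to the
gradient), gradients clipped **by value** at 0.1 — the natural reading of
clipping "gradient values"; global-norm clipping is available behind a
flag. Up to 150 epochs with early stopping on validation loss (patience 10
by default) and best-validation parameters restored at stop; the monitored
quantity and the restore rule are this package's choice, as is the default
seed set {0, 1, 2}. Each training image is re-augmented on every pass and
the training set is iterated `repeats_per_epoch` times (default 8) per
epoch.

Augmentation: horizontal flip (p = 0.5); rotation drawn uniformly from
{0°, 90°, 180°, 270°} (all four right angles are included); brightness,
contrast and saturation jitter each with p = 0.5 at factor ±0.25 and hue
shift with p = 0.05 at ±0.05 — the magnitudes are package defaults, exposed
in the config; optional fixed-size random crops for higher-resolution
datasets. Geometric transforms apply identically to image and mask; colour
jitter never touches the mask.

## Cross-validation

Five split schemes: unstratified k-fold; k-fold stratified by time point or
by biomaterial condition (per-fold label counts within one image of
proportionality, via stratified fold assignment); 4-fold by week, where
each validation fold is exactly one week's images; and train-on-weeks-1/2/4,
validate-on-week-8. All schemes are pure functions of (ids, labels, seed).
The experiment harness trains every (variant, fold, seed) triple — 5 folds
× 3 seeds = 15 runs per variant — writes one JSON record and checkpoint per
run, and resumes from those records if interrupted.

## Metrics

Accuracy, precision, recall, specificity, Dice (= F1), positive-class IOU,
and overall IOU. Overall IOU is the unweighted mean of the positive-class
and background-class IOUs (the reference material names but does not define
it). Zero-denominator convention: a metric whose defining sets are empty is
1 when the prediction is vacuously correct (no positives exist and none
were predicted), else 0 — this rewards correct all-negative predictions and
matches common segmentation toolkits. Metrics are macro-averaged (per
image, then per fold, then mean ± sample SD across fold×seed runs); micro
pooling is deliberately not the default since per-image averaging matches
how per-run summaries are reported.

## Physical areas

`FA_full = FA_down · (IA_full / IA_down) · RL²` maps positive pixel counts
in the downsampled mask to full-resolution area in µm², where RL is the
microscope calibration in µm/px. A missing calibration is an explicit
error, never a silent default. Group summaries report n, median and the
25th/75th percentiles with linear (type-7) interpolation. Areas are not
normalized by section or scaffold area.

## Synthetic data

The generator emulates stained sections: a stain-palette base colour
(eosin pink / hematoxylin purple for H&E; blue/red for trichrome) modulated
by smooth low-frequency colour noise, plus fine Gaussian pixel noise
(σ = 0.02); adipocytes as non-overlapping white-filled ellipses (axes 4–12
px by default) with a darker membrane ring (1.5 px), and ground truth
masks equal to the ellipse interiors. Placement is rejection-sampled until
the realized adipose fraction falls in the requested range, which reaches
down to the adipose-poor regime (< 1% positive pixels); an infeasible
range raises a generation error naming the constraint. Weeks {1, 2, 4, 8}
and four condition labels are assigned cyclically so every stratified
scheme is exercisable, and generation is a pure function of its spec (two
runs with the same seed produce byte-identical files).

What the generator does **not** emulate: real membrane texture and nuclei,
scaffold pores (the main false-positive mode in real sections), staining
variability across labs, out-of-focus regions, and annotation noise. Tests
passing on this data therefore demonstrate that the architecture, losses,
splits and bookkeeping behave as specified — not that the models reach any
particular accuracy on real histology.

## Desk-scale study conditions

The repository's end-to-end checks run entirely on CPU: 32 synthetic
64×64 images (24 train / 8 validation), a depth-2, 8-base-channel
multiply-fusion histogram network with 4 bins per block (16 bins cannot
divide the tiny channel counts), batch 8, one pass per epoch, at most 20
epochs with patience 5, three seeds. Under these conditions validation
dice exceeds 0.8 for every seed and predicted physical areas correlate
with the generator's ground truth at Pearson r > 0.95. The default-scale
parameter accounting (depth 4, base 64) is exact and independent of
training.

## Limitations

- The autodiff engine implements exactly the operator set these networks
  need; it is float64-only, single-device, and makes no attempt at
  performance parity with mainstream frameworks.
- Elementwise fusion requires the halved-bottleneck width convention; the
  layer accounting of the original architectures is not printed anywhere
  authoritative, so other conventions would shift the parameter counts.
- Window sizes and bin counts are fixed per model, not searched; multiscale
  or learnable windows are out of scope.
- Binary (one positive class) segmentation only.
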
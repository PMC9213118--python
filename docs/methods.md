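# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
and design decisions a maintainer would want written down.

## Architecture

All blocks preserve spatial resolution: there is no pooling or upsampling
anywhere, so an H×W input yields an H×W probability map. This is the only
design under which the channel concatenation in the encoder, the pixel-wise
calibration product in the decoder, and the three-way decoder concatenation
are simultaneously shape-consistent.

**MSF encoder.** Five parallel branches over the normalized RGB input. The
rate-1 branch is a 1×1 convolution (pixel-wise, global); branches 2–5 are
3×3 dilated convolutions at rates (3, 6, 12, 18). The dilation convention:
rate r means taps spaced r pixels apart (r−1 gaps), with "same" zero padding
of r per side, so rate 1 degenerates to an ordinary convolution. A
dilated 3×3 at rate 2 is tap-equivalent to a dense 5×5 kernel with zero
interior weights (asserted in the tests). Each branch ends with a
conventional 3×3 filtering convolution (branch-channels → branch-channels,
G = 128 by default), batch norm and ReLU. Branch outputs are concatenated on
channels into a 5G map.

**scSE attention.** Channel gate: global average pool → dense bottleneck
(reduction 2, minimum width 1) → ReLU → dense expansion → sigmoid. Spatial
gate: 1×1 convolution to one channel → sigmoid. The two recalibrated maps
combine by addition, so with both gates saturated the block tends to twice
the input — the saturation limit the tests assert. Placement is
configurable: per-branch ("I"), after fusion ("II"), both, or none. The
default is "II", the best-reported variant of the ablation family.

**ASCS bridge.** Parallel 3×3, 1×3 and 3×1 convolution+BN+ReLU paths from
the input, each to 3 channels. The asymmetric pair holds exactly 2/3 the
weights of a square 3×3 kernel at equal channels. Fusion is element-wise;
because the source formula for the fusion is typographically corrupted, two
readings are provided behind `fusion_rule`:
`literal_product` (default): Ŷ = (Y¹ˣ³ ⊙ Y³ˣ³) ⊙ (Y³ˣ¹ ⊙ Y³ˣ³);
`sum_product`: Ŷ = (Y¹ˣ³ + Y³ˣ³) ⊙ (Y³ˣ¹ + Y³ˣ³). The ambiguity is kept
explicit as a switch rather than silently resolved. Dropout (rate 0.1,
configurable) follows the fusion and is disabled at inference.

**Decoder.** Ỹ′ = ReLU(BN(1×1-conv(Ỹ))) compresses the 5G encoder map to
the bridge width (3). The calibration multiplies Ỹ′ with the *bridge* map Ŷ
pixel-by-pixel — the compressed map cannot be multiplied by the 5G encoder
map, so the prose reading is the only shape-valid one. Concatenating
(Ŷ, Ỹ′, Ỹ″) gives 9 channels; a final 1×1 convolution + BN + sigmoid
produces the single-channel prediction.

**Deep supervision.** Ŷ, Ỹ′ and Ỹ″ are 3-channel maps and cannot be
compared to a 1-channel label directly, so each passes through its own
1×1-conv + sigmoid head. The composite loss is
BCE(Y_pred) + μ·BCE(head(Ŷ)) + ν·BCE(head(Ỹ′)) + ξ·BCE(head(Ỹ″)) with
μ, ν, ξ ∈ [0,1], μ+ν+ξ = 1 (enforced to 1e-9); the default is the uniform
(1/3, 1/3, 1/3) since only the constraint is prescribed.

## Optimization

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with the LRAA two-stage schedule:
for the first τ = s//2 of the planned s epochs (defaults η = 1e-4, s = 150)
the rate is constant; afterwards, an epoch whose training loss fails to
improve on the previous epoch halves the rate, floored at 1e-6. The interior
of the published schedule exists only as an unavailable figure; this
plateau-halving rule implements its stated intent (adapt to the loss change
of adjacent iterations) and is pluggable. "Iteration" is read as epoch. The
best model is selected by validation Dice (pooled counts); batch size
defaults to 8.

## Losses, metrics, conventions

Cross-entropy clamps probabilities to [1e-7, 1−1e-7]; the final sigmoid also
clamps its output to that open interval so saturated float32 predictions
remain strictly inside (0, 1). The backward pass fuses sigmoid and BCE into
the exact (p − y)/n logit gradient, avoiding the p(1−p) cancellation.
IoU = TP/(TP+FP+FN) and Dice = 2TP/(FP+2TP+FN) over pixel counts, with the
empty-vs-empty 0/0 case defined as 1; micro-averaging (pooled counts) is the
default, macro (per-image mean) is available. Predictions binarize at 0.5.
Batch norm uses ε = 1e-5, momentum 0.1, biased batch variance, running
statistics at inference. Weights initialize Kaiming-normal (fan-in); all
randomness (init, dropout, shuffling, data synthesis) flows from explicit
seeds, and inference is bit-deterministic.

## Synthetic data

The generator emulates the three troublesome lesion morphologies as darker
elliptical blobs on a skin-toned, lightly textured background: per category
(area fraction range, boundary-noise amplitude) =
small ((0.005, 0.05), 0.08), prominent ((0.15, 0.45), 0.08),
irregular_edge ((0.08, 0.30), 0.35). The boundary is an ellipse whose radius
is modulated by seeded angular harmonics (orders 2–5), giving a star-shaped
— hence connected — region with an exact analytic mask; a fixed-point
correction pulls the realized area into the category's range, and an
infeasible range raises. Thin dark Bézier arcs imitate hair artifacts
(probability 0.3). What it does **not** emulate: real pigment-network
texture, multi-focal or ring-like lesions, ruler markings and color-patch
artifacts, specular highlights, and the low lesion/skin contrast that makes
ISIC hard. Passing the learning checks therefore demonstrates that the
architecture, gradients, schedule and metrics are correct and that the model
can learn a nontrivial segmentation — not that it reaches published
benchmark accuracy on real dermoscopy data, which would require the ISIC
images and full-scale training.

## Data pipeline

ISIC-style directories (`images/`, `masks/`, matching stems, the
`_segmentation` suffix tolerated) are split by seeded shuffle with default
fractions 1814/260/520 out of 2594 (≈ 0.699/0.100/0.200). Images resize
bilinearly to the working resolution (default 224) and standardize per
channel by training-split statistics (ImageNet constants available by flag);
masks resize nearest-neighbour so they stay binary. Augmentation applies one
geometric transform (rotation ±30°, centre crop at scale 0.8–1.0) to image
and mask alike and photometric jitter (brightness/contrast/saturation/hue,
amplitude 0.2) to the image only. Coordinates are row-major, origin
top-left, 0-based.

## Scaled-down study conditions

CPU-side checks run the architecture at reduced width and resolution: the
learning check trains the G = 8 variant on 200/50 synthetic 64×64 images
with Adam at 1e-3 for at most 20 epochs (early-stopped once validation Dice
reaches 0.85). The width/resolution reduction keeps the full block structure
while making the run take seconds; 1e-3 is the conventional Adam rate for
small from-scratch models, whereas the 1e-4 default belongs to the
full-scale 150-epoch schedule. Unit tests use 6×6–16×16 inputs, where the
NumPy convolutions are cross-checked against explicit loop oracles (1e-5)
and all gradients against central differences.

## Known limitations

- Pure-NumPy execution: a default-width 224×224 forward pass takes seconds
  on one CPU; full-scale 150-epoch training at 224×224 is out of practical
  reach, so published-benchmark numbers are not asserted anywhere.
- Parameter counts are reported, not asserted against any external table:
  the default G = 128 model has ~1.17 M trainable parameters, dominated by
  the encoder's per-branch filtering convolutions, whose exact channel plan
  is underdetermined by the source description.
- The `literal_product` bridge multiplies four ReLU outputs, which zeroes
  most bridge pixels early in training; the deep-supervision heads keep
  gradients flowing, and `sum_product` is available where a denser bridge
  is wanted.
- The k-fold cross-validation used in the original protocol is simplified
  to a fixed seeded split; a grid ablation driver (`msfanet ablate`) stands
  in for the published rate/attention ablations on synthetic data.
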
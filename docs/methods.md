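# Methods

## Problem and scope

`lesionseg` segments a single skin lesion from a dermoscopic RGB image. The
pipeline is: morphological hair removal, resizing and normalization,
optional paired augmentation, an attention-gated encoder–decoder network
with an order-statistics bottleneck layer and iterative decoder feedback,
trained with a hybrid Dice + binary-cross-entropy objective, and a standard
segmentation metric suite (Dice, IoU, pixel accuracy, precision, recall,
ROC AUC). A seeded synthetic-scene generator makes every stage testable
without downloading clinical data.

## Preprocessing

Hair strands are thin dark curvilinear occluders. Detection uses the
black-hat transform, `closing(I) − I`, with a 17×17 rectangular structuring
element: closing removes dark structures narrower than the element, so the
residual is large exactly on strands. The response is binarized with a
*strict* threshold (`response > T`, T = 50); thresholding is monotone in T
by construction. Rank filters use replicate-edge semantics, which is
identical to evaluating max/min over the in-image part of each window; the
test suite pins this convention against a windowed brute-force oracle.

Detected pixels are reconstructed by fast-marching inpainting: unknown
pixels are visited in order of increasing Euclidean distance from known
territory (the fast-marching arrival time under uniform speed) and filled
with the inverse-distance-weighted mean of known pixels within a
configurable radius (default 3 px — strands are thin, and a small radius
avoids blurring lesion texture). Pixels outside the mask are returned
bit-exact. Degenerate input (an all-foreground mask) is rejected.

Choices the data formats leave open, fixed here: grayscale for detection is
the standard Rec. 601 luminance (hair detection is intensity-based);
hair removal runs at native resolution *before* resizing, because thin
strands vanish under downsampling; images are resampled bilinearly and
divided by 255, masks with nearest-neighbour and re-binarized at 0.5.

Augmentation draws one geometric transform per (image, mask) pair from a
seeded stream — rotation ±30°, width/height shifts ±10%, shear 0.2
(radians), zoom in [0.6, 1.4], horizontal/vertical flips — and applies it
identically to both, with reflect padding for images and zero fill for
masks (zero fill avoids phantom lesion pixels). With all ranges zero and
flips off the operation is the exact identity. Augmentation is applied
online to the training stream only.

## Network

Input is H×W×3 in [0, 1] (default 256×256; any size divisible by the pooling
stride works). The default topology:

- **Encoder**: two blocks of (3×3 conv → ReLU) × 2 followed by 2×2 max
  pooling, with 32 then 64 filters.
- **Bottleneck**: 3×3 conv (128 filters) → ReLU → order-statistics layer →
  3×3 conv (128 filters) → ReLU. The second convolution is the "feature
  extractor" consuming the augmented (C+2)-channel tensor.
- **Order Statistics Layer (OSL)**: per pixel, the mean of the k smallest
  and the k largest channel activations (k = 1 by default, i.e. plain
  min/max), both normalized by `large + ε` (ε = 1e−7), appended as two extra
  channels. The layer has no learnable parameters, is permutation-invariant
  in the channels, scale-invariant up to ε, and expects nonnegative input —
  it sits directly after a ReLU and rejects negative input at run time.
  Gradients route 1/k to each selected channel entry.
- **Attention gates** on each skip connection: with skip x and gating
  signal g (the decoder input one level below, upsampled),
  α = σ(ψ(ReLU(θ(x) + φ(g)))) with 1×1 convolutions θ, φ, ψ and an
  intermediate width of half the skip channels; the gated skip is α ⊙ x.
- **Decoder**: per level, 2× nearest-neighbour upsampling + 3×3 conv
  (chosen over transposed convolution to avoid checkerboard artifacts),
  concatenation with the gated skip (and feedback features, below), then
  conv → BatchNorm → ReLU twice, a final 3×3 conv + ReLU, and dropout
  (rate 0.3). Decoder widths mirror the encoder (64, 32).
- **Head**: 1×1 convolution + sigmoid → per-pixel lesion probability.

**Iterative feedback.** The forward pass may run T ≥ 1 times (default 2)
with one shared weight set. On pass t > 1, each decoder block additionally
concatenates the previous pass's output at the same level, projected to a
small channel budget (8) by a 1×1 convolution. Pass 1 concatenates zeros,
so a single pass is *exactly* the feedback-free computation — the test
suite asserts this reduction and that the feedback projections are inert at
T = 1. Gradients flow through all passes (no stop-gradient): with T = 2 the
cost is roughly twice a single pass and the refinement signal reaches the
first pass's weights.

**Batch-norm statistics under feedback.** The same BatchNorm layers see
different activation distributions on each pass (pass 1 has zero feedback
features). A single running-average buffer would mix the passes and match
neither at evaluation time — in development this collapsed evaluation-mode
accuracy while batch-statistics mode was fine. Each pass index therefore
keeps its own running mean/variance (the affine parameters are shared), and
the training loop re-estimates the buffers before each validation pass with
dropout disabled and exact cumulative averaging over a deterministic
training subsample (8 batches by default). Training/evaluation mode is
always explicit; evaluation uses the per-pass running estimates.

All switches (attention, OSL, feedback) are independent; with all off the
model is a plain U-Net baseline of the same depth. Weight initialization is
He-normal from a seeded generator; checkpoints are a `.npz` of arrays plus
a JSON config with a schema version.

## Loss and metrics

The training objective is
`w_dice · (1 − softDice) + w_bce · BCE` with `w_dice = w_bce = 0.5`
(the weighting is a package choice; equal weights are the neutral default).
Soft Dice uses probabilities directly with additive smoothing 1 in
numerator and denominator; probabilities are clipped to [1e−7, 1 − 1e−7]
inside the BCE term.

Evaluation metrics: Dice 2|A∩B|/(|A|+|B|) and IoU |A∩B|/|A∪B| (which
satisfy IoU = DC/(2−DC), pinned to 1e−12 in tests), pixel accuracy,
precision, recall, and pooled-pixel ROC AUC via the midrank statistic
(single-class truth is reported as undefined and excluded). Conventions
fixed here: predicted masks binarize at 0.5; Dice/IoU aggregate as
per-image means while PA/precision/recall/AUC pool pixels (the report
records the convention; both are computable); both-empty masks score 1.0;
degenerate precision/recall denominators score 1.0 when the corresponding
error count is zero, else 0.0.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e−4, batch size 16, up to 150
epochs, validation-loss plateau decay (factor 0.1, patience 10, floor
1e−7), early stopping after 15 consecutive non-improving epochs, and
best-validation-loss weights restored at the end. "Improvement" means the
monitored loss falls by more than min_delta = 1e−4; both monitors use
validation loss. Histories record per-epoch train/validation loss and pixel
accuracy, validation Dice, and the current learning rate. Manifest
splitting is a seeded shuffle followed by contiguous assignment to
(train, val, test) counts.

The ablation harness trains five configurations — baseline, +attention,
+OSL, +feedback, full — with shared data, seed and epoch budget, and emits
one row each (Dice, IoU, accuracy, parameter count). Parameter counts obey
baseline ≤ each single-module variant ≤ full.

## Synthetic scenes

Each scene is a skin-tone background (base colour with per-scene jitter, a
smooth directional illumination ramp of 5–15 intensity units, Gaussian
pixel noise σ = 4), one lesion, and optionally hair. The lesion boundary is
an ellipse whose radius is modulated by harmonics of order 2–5 with total
amplitude ρ ≤ 0.5; this keeps the region star-shaped, hence a single
connected component, and at ρ = 0 the rasterized area matches πab to a few
percent. The lesion interior is darkened by a contrast Δ (50–75 by default;
a configurable fraction of scenes, default 30%, uses a low-contrast Δ of
15–30) with a 2 px feathered border and intra-lesion texture noise. Hairs
are quadratic Bézier strands crossing the frame, width 1–3 px, drawn
darker than their surroundings by 80 units — chosen so the 17×17 black-hat
response on strand pixels clears the detection threshold of 50, which is
exactly the operating regime the preprocessing constants assume. Strand
pixels are recorded as a separate occluder truth, never merged into the
lesion mask. Generation is a pure function of (parameters, seed).

What the generator does *not* emulate: multi-lesion scenes, ruler marks and
gel bubbles, vignetting, colour constancy problems, camera noise structure,
and the texture statistics of real dermoscopy. Passing tests therefore
demonstrate correct mechanics and learnability of the architecture, not
clinical performance.

## Problem sizes used by the checks

The convergence checks train the full model at reduced scale: 64×64 scenes,
200 train / 50 validation, encoder filters (8, 16), bottleneck 32, batch 8,
learning rate 1e−3 (the standard Adam regime for short small-model runs),
15 epochs; the ablation harness runs five configurations for 3 epochs on
100/25 of the same scenes. The hair-removal check uses twenty 192×192
scenes so the 17×17 element runs at native strand scale. Oracle
equivalences run on 8×8×16 tensors (OSL), 32×32 images (morphology), and
≤64-pixel instances (metrics).

## Known limitations

- The network stack is pure NumPy; it is single-process and sized for
  method validation, not for full-resolution 150-epoch training runs.
- The fast-marching inpainter uses inverse-distance weighting only (no
  directional/level-set term); adequate for strands 1–3 px wide.
- Feedback beyond T = 2 passes multiplies runtime linearly and has no
  per-pass running statistics until a pass index has been trained once;
  evaluation falls back to the highest trained pass index.
- Per-channel (rather than luminance) hair detection is not implemented.
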
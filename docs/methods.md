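# Methods

## Model

HASA-ResUNet is a 2-D encoder–decoder segmentation network. The encoder has
`depth` stages (default 5) of residual blocks with 2×2 max pooling between
stages and channel width doubling per stage (defaults 64→1024; the tiny CPU
preset uses 8→128 with one residual block per stage). The decoder upsamples
with kernel-2 stride-2 transposed convolutions, concatenates the
matching-scale skip, and fuses with two 3×3 conv+BN+ReLU layers. The final
1×1 convolution produces K = 11 logits per pixel, normalized by a softmax.
Input spatial dims must be divisible by 2^(depth−1); violations raise a
shape error rather than silently cropping.

Two attention families are inserted, each independently switchable (the
four on/off combinations are the ablation variants):

**HFEF** sits on the three highest-resolution skips (levels 1–3, spatial
kernels 3/5/7) and on the bottleneck output (level 4, kernel 9). Within a
block: (1) channel attention — a per-pixel channel MLP with a C/4
bottleneck, realized as 1×1 convolutions because a weight matrix shared
across spatial positions is the only reading that keeps the parameter count
independent of H and W; its sigmoid gates the input. (2) channel shuffle —
reshape the channel axis to (4, C/4), transpose, flatten; the standard
interleaving that lets information cross group boundaries. (3) spatial
attention — conv_k to C/4, BN, ReLU, conv_k back to C, BN, sigmoid gate.
Convolutions followed by BN carry no bias (redundant parameterization).

**ASA** sits between the last decoder feature map and the classification
convolution, once (not per stage). The atrous pyramid splits channels into
4 equal groups and convolves group i with a 3×3 convolution of dilation
r_i ∈ {1, 6, 12, 18} and padding r_i (spatial dims preserved); a plain
channel split is used with no 1×1 compression beforehand — the compression
to C/4 per branch is exactly what the split provides. Squeeze-and-
excitation pools the pyramid output globally, passes it through a C→C/4→C
MLP, and a softmax over the full C-length logit vector (configurable to
per-group) yields channel weights that multiply the pyramid features.
Because the weights are a probability vector, the head's input is scaled by
~1/C on average; see "Known limitations".

## Loss and metrics

The training loss is `w₁·CE + w₂·Dice` with w₁ = w₂ = 0.5. Cross-entropy is
categorical (−log p_true averaged over pixels, probabilities clamped at
1e-7); a binary two-term mode is retained behind a flag for the K = 2 case.
Soft Dice is computed per class between the probability channel and the
one-hot target, pooled over the batch, then macro-averaged over all K
classes (background included by default; both choices are exposed). A
smoothing ε = 1 in numerator and denominator keeps classes absent from a
batch at Dice ≈ 1 instead of 0/0, so suppressed absent classes contribute
no loss.

Evaluation metrics derive from one-vs-rest pixel confusion counts pooled
over the whole evaluation set (micro per class), then macro-averaged across
classes; pooling was chosen over averaging per-image scores because it
weights every pixel equally and is stable for structures that appear in few
slices. Classes with TP+FP+FN = 0 (absent from prediction and truth alike)
are excluded from macro means. Means are reported both with and without the
background class, since reporting conventions differ.

## Synthetic phantom

The generator emulates the statistical structure of sagittal T1 knee
slices, not their anatomy: skin as a thin annulus at the border, femur and
tibia as large ellipses above/below a joint gap, menisci as thin crescents
in the gap, cruciate ligaments as thin oriented bands crossing it, patella
and fibula as small ellipses, all jittered in position/size/orientation.
Structure presence is Bernoulli per class (skin/bones ~1.0, menisci 0.5,
patella/patellar ligament/fibula 0.4, cruciate ligaments 0.25), chosen so
small structures are also low-frequency, as in real slice stacks. Painting
order is fixed (bones < skin < small structures) so masks are
deterministic. The intensity image is per-class means plus texture noise,
Gaussian-blurred (σ = 1.2 px default) to soften boundaries — the label map
stays crisp — then global noise and a per-image brightness/gain wobble are
added. With the default geometry the background holds ~66% of pixels and
each meniscus class under 2%, giving the imbalance ordering
background ≫ bones ≫ menisci/ligaments.

What the phantom does **not** model: MRI physics (coil inhomogeneity,
sequence-dependent contrast), anatomically correct shapes, inter-slice 3-D
continuity, pathology. Tests that pass on phantoms therefore demonstrate
that the pipeline is mechanically and statistically sound under imbalance
and blur — not clinical-grade accuracy on real knees.

## Training

Adam (β = 0.9/0.999, ε = 1e-8), batch size 6 (tiny preset 4), up to 100
epochs with early stopping: training halts when the validation macro DSC
fails to exceed the running best by ≥ 1e-5 for 5 consecutive epochs, and
the best-epoch weights are restored. The monitored DSC excludes the
background class by default so the monitor stays sensitive to small
structures. Online augmentation (random rotation ±15°, Gaussian noise,
elastic deformation, brightness shifts; each with probability 0.5) applies
geometric transforms identically to image and mask (nearest-neighbor for
the mask, so labels stay in the codebook) and intensity transforms to the
image only. Images are z-scored per slice at load time; the 8:1:1
train/validation/test split is random at the case level so slices of one
acquisition never straddle splits.

The full-scale configuration keeps the reference learning rate 1e-4. At
the tiny CPU scale used by the test suite, Adam's per-step parameter
displacement is bounded by the learning rate, so a useful fit within a few
hundred steps requires lr 1e-3; the package's sanity harness
(`overfit_single_batch`: 4 phantoms, tiny preset, no augmentation) uses
lr 1e-3 and 900 steps, at which point the hybrid loss falls below 0.15
(and to ~0.005 by 1200 steps).

## Numerical choices

- Working precision is float32 (the field standard for CNN training);
  float64 is available via `hasaseg.nn.using_dtype` and is used by the
  oracle and finite-difference tests.
- Convolutions are stride-1 with symmetric zero padding (k−1)/2·dilation;
  the input gradient of a convolution is computed as a convolution with the
  flipped, channel-transposed kernel, avoiding scatter-adds.
- BN uses batch statistics in training and running statistics (momentum
  0.1, ε = 1e-5, unbiased running variance) at inference; full-batch
  statistics, not per-group.
- Softmaxes subtract the row maximum before exponentiation.
- Max-pool ties resolve to the first element in row-major order; argmax
  ties in `predict_mask` resolve to the lowest class index.
- He-normal initialization for convolution and linear weights, zeros for
  biases, ones/zeros for BN scale/shift; all init draws come from one
  seeded generator per model, so a seed reproduces parameters bitwise.
- z-scoring floors the standard deviation at 1e-8 (constant images map to
  zeros); splits need ≥ 3 cases.

## Test-scale choices

The suite exercises everything at CPU scale: the tiny model preset
(widths 8→128, one residual block per stage), phantoms at 96×96 or 64×64,
and short training budgets (the ablation harness: 200 phantoms at 64×64,
batch 4, lr 1e-3, 8 epochs, no augmentation, 3 seeds). These sizes are the
package's reference test conditions and are deliberately small enough to
run on a single core.

## Known limitations

- The ASA softmax produces channel weights summing to 1, so the
  classification head receives features attenuated by ~1/C on average.
  The head compensates during training, but this takes thousands of Adam
  steps: at short CPU budgets the attention-augmented model converges
  more slowly than the plain ResUNet baseline and can score below it,
  even though it keeps improving after the baseline plateaus. Orderings
  measured at short budgets therefore do not reflect orderings at
  convergence.
- The encoder width/stage plan of the full-scale reference model is a
  design choice (64→1024, two residual blocks per stage); other plans with
  the same depth are equally consistent with the architecture description.
- 2-D slices only; no 3-D context, no pretrained encoders, no deep
  supervision, no mixed precision or multi-device training.
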
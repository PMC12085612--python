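# Methods

This note documents the models, numerical choices and limitations of
`ihsnet`.  It covers only what the code computes; all numbers quoted
are produced by the test suite or `scripts/acceptance.py`.

## Network architecture

MUNet is a fully convolutional encoder–decoder with a feature pyramid
and two heads.

**Encoder.**  Five blocks; block *k* is a stride-2 3×3 CBL
(convolution → batch norm → leaky ReLU) followed by a stride-1 3×3 CBL.
The stride-2 convolution replaces pooling.  With `base_channels = B`
the level-*k* map C_k has S/2ᵏ spatial size and B·2ᵏ⁻¹ channels; at
the reference width B = 64 and S = 256 this gives C1…C5 =
128×128×64, 64×64×128, 32×32×256, 16×16×512, 8×8×1024.  The stride-2
convolutions use padding 1: with padding 0 a 3×3/stride-2 convolution
maps 256 → 127, which contradicts the halving rule and the printed
pyramid sizes, so the sizes win.  Two convolutions per block is the
minimal structure consistent with the CBL stacking; the count is not
otherwise pinned down.

**Decoder.**  Starting at C5, each stage does: bilinear ×2 upsampling →
concatenation with the matching C_k → 1×1 CBL that compresses the
channels back to B·2ᵏ⁻¹ → 3×3 DBL refinement.  The stage outputs are
the decoder maps X4…X1 (X5 ≡ C5).  A final ×2 upsampling and 1×1
convolution produce the 6-channel logit map; per-pixel softmax over
{background, EDH, IPH, IVH, SAH, SDH}.  Upsampling is interpolation +
convolution rather than transposed convolution (cheaper, no
checkerboarding); both bilinear and nearest are implemented
(`upsample_mode`), bilinear is the default.  A single fused decoder
produces all six channels; per-level auxiliary heads were considered
and rejected as redundant with the fused map.

**Classification head.**  Global average pooling of C5 → FC(16B → 4B)
→ leaky ReLU → FC(4B → 5) → softmax.  The hidden width 4B (256 at the
reference width) was chosen empirically; wider heads overfit the
desk-scale task.  No dropout: at the short desk-scale budget it slowed
convergence without improving held-out accuracy.

Both heads are softmax: the subtype labels are mutually exclusive
(one lesion per slice), so sigmoid outputs would be inconsistent with
the labeling.

**Numerical details.**  float32 NCHW throughout; He-normal
initialization seeded from the model config; batch norm eps 1e-5,
momentum 0.1 (eval mode uses exponential running statistics); leaky
slope 0.001; Adam betas (0.9, 0.999), eps 1e-8.  Argmax ties (e.g. a
uniform probability map) break toward the lowest class index, which
makes prediction deterministic.  The network is implemented in numpy
with hand-written backpropagation (im2col convolutions, separable
interpolation matrices for upsampling whose backward pass is the exact
adjoint); every gradient path is checked against central finite
differences in the test suite.

## Loss

Per batch, `L = L_fl + λ·L_ms` with λ = 1 by default (λ is exposed in
config; λ = 0 disables the mask term, and the focal term can likewise
be neutralized for a pure-Dice objective).

* Focal loss `L_fl = −α(1−p_v)^γ log p_v`, averaged over the batch;
  γ = 2, α = 0.25 defaults (the canonical settings; not otherwise
  specified).  p_v is clamped at 1e-12 and the clamp is logged.
* Dice loss `L_ms = 1 − D̄` from the softmax probabilities.  Soft Dice
  per (image, class) uses probability-weighted intersections with
  smooth = 1.0 in numerator and denominator (guards empty masks).  The
  default averaging ("image" mode) is over the background channel plus
  the foreground classes *present in each image*.  Two alternatives
  were rejected: averaging over all five foreground channels per image
  has a degenerate minimum — predicting an empty mask scores Dice ≈ 1
  on the four absent classes, and small networks find it — and
  batch-pooled per-class averaging ("batch" mode, kept as a switch)
  trains noticeably worse on per-image class identity.
* Reported (non-loss) Dice uses smooth = 0 with empty-vs-empty
  defined as 1.

Gradients of both terms are derived analytically through the softmax
(`dL/dz = p·(g − Σ g·p)`), so the heads receive exact logit gradients.

## Synthetic phantoms

A phantom is an 8-bit S×S slice (S a multiple of 32) with a dark
background (~8), an elliptical skull ring (~235, outer radii 0.46S /
0.42S, thickness 0.035S), Gaussian-smoothed parenchymal texture
(105 ± 12), one lesion at 185 (hyperdense blood: above parenchyma,
below bone) and additive Gaussian noise (sd 4 by default).  Subtype
priors: IVH — blob near the image center; IPH — blob in the
mid-parenchyma, kept clear of the rim; SAH — streak of thickness
0.02S tracking the inner table at 0.90 of its radius; SDH — crescentic
band hugging the inner table, thickness 0.06S, tapering to its tips;
EDH — lens formed by two intersecting discs at the table.  A
size-correction loop keeps the rasterized lesion area within ±40% of
`lesion_scale`·S² despite clipping against the skull.  The SDH band
and the IPH rim margin were shaped so that the five classes are
geometrically well separated at desk resolution — the design goal of
the phantom task is an *easy* benchmark every stage can demonstrably
learn.

Synthetic patients group k consecutive slices of one class (default
k = 30, matching roughly one CT series per patient), which gives the
patient-wise split something to respect.

What the phantoms do **not** emulate: Hounsfield physics and windowing,
anatomy (ventricles, sulci, falx), partial-volume and beam-hardening
artifacts, multi-lesion slices, inter-slice correlation, or realistic
class-conditional intensity distributions.  Passing the phantom suite
therefore demonstrates that the pipeline's machinery — shapes,
gradients, bookkeeping, determinism — is correct and that the model
can learn a separable segmentation/classification task; it says
nothing about performance on clinical CT.

## Preprocessing

Resizing is bilinear via Pillow, square-only (1:1 inputs), no
cropping.  CLAHE: per-tile 256-bin histograms (8×8 grid default),
clipped at `clip_limit` × (tile pixels / 256) with the excess
redistributed uniformly (integer remainder to the lowest bins), CDF
mappings blended bilinearly between tile centers; border tiles come
from reflect padding.  Identical preprocessing is applied to every
split.  Note that CLAHE *raises* parenchymal (local) contrast while
slightly *reducing* global pixel std on phantoms, because the extreme
skull/background modes are compressed; the test suite asserts the
local property.  Network inputs are scaled to [0, 1] and replicated to
3 channels to match the declared 256×256×3 input.

## Class balancing

SMOTE on flattened preprocessed grayscale images of the training split
only; k = 5 neighbors by default (Euclidean).  Masks for synthetic
images interpolate the two parents' binary masks with the same u and
threshold at 0.5 — the source method does not define mask synthesis,
so this rule is an explicit package decision isolated behind
`SmoteConfig.mask_rule`.  Synthetic rows are flagged in the manifest;
test rows are never parents and never altered.

## Training

Reference defaults (`TrainConfig`): input 256, lr 1e-4, drop factor
0.5 on a validation plateau, 60 epochs, batch 32, Adam.  Validation is
10% of the *training patients* (patient-wise, seeded); "best" model =
lowest validation loss (switchable to accuracy), restored at the end
of training and checkpointed as `.npz`.  The plateau rule: no
improvement > 1e-4 for `patience` epochs (default 5) → lr ×= 0.5.
Non-finite loss aborts with a diagnostic.  With a fixed seed the full
run — patient shuffle, batch order, init — is bit-reproducible.

**Desk-scale study** (`ihsnet.experiments.desk_scale_study`): 50
phantoms per class at 64×64 (200 train / 50 test after the 80/20
patient-wise split), base_channels 8, 10 epochs.  At this budget
(~500 updates) the reference lr 1e-4 barely moves the network, so the
study uses lr 5e-3, batch 4, focal α = 1, patience 3 — settings chosen
by a sweep over development seeds and recorded here as the study's own
protocol.  Typical results: final training loss 0.2–0.35 from ~1.5,
held-out subtype accuracy 0.78–0.96, held-out mean foreground Dice
0.55–0.8 (per-slice Dice of the true class, averaged per class then
across classes).  The accuracy figure is stochastic at n = 50; most
seeds land at 0.84–0.9.

## Evaluation

One-vs-rest reduction of the K×K confusion matrix; the five rates
follow the standard formulas with 0/0 reported as 0 and flagged.
Per-class segmentation Dice/IoU are averaged per slice (each test
slice contributes the Dice of its true class), not pooled over pixels
— the alternative pooling is a one-line change but per-slice averaging
weights small lesions equally.  AUC is trapezoidal over the
one-vs-rest ROC (sklearn's curve points); tests verify it against the
Mann–Whitney pair-count statistic.  Report tables round to 2 decimals,
half-up.  Per-class report rows carry both one-vs-rest accuracy and
recall under distinct labels, since a per-class "accuracy" column is
ambiguous between the two.  An ICC(2,1) implementation is included as
an extra agreement statistic but is not validated against any external
value.

## Known limitations

* The numpy network is CPU-only and desk-scale; the reference-width
  256×256 configuration forward-passes in seconds but full 60-epoch
  training at that width is far outside this implementation's intended
  use.
* NIfTI support is read-only (axial slicing with per-slice min-max
  rescaling); PNG is the working format.  No DICOM, no Hounsfield
  windowing.
* SMOTE on raw pixels interpolates images linearly, which blurs
  texture; it reproduces the balancing protocol, not a recommendation.
* The phantom generator's realism limits are listed above; none of the
  reported phantom metrics transfer to clinical data.
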
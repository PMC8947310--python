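# Methods

## Problem and model

The package classifies segmented tongue photographs into the five
diagnostic tongue-body colours of Traditional Chinese Medicine — light
red, red, deep red, light white, cyan. The classifier is a capsule
network with a residual convolutional front end ("TongueCaps"): capsule
activities are vectors whose length encodes the probability that a class
is present, so the final prediction is simply the longest class capsule.

The forward pass, for an L×L×3 HSV image:

1. **Stem and residual feature extractor.** A 7×7 Conv-BN-ReLU (3
   kernels, 'same' padding), 3×3 stride-2 max-pooling, then six residual
   blocks (3×3 convolutions). A block computes `H(x) = ReLU(F(x) + shortcut(x))`
   with `F = ConvBNReLU → Conv-BN`; variant *a* uses an identity shortcut
   (requires unchanged channels, stride 1), variant *b* convolves the
   shortcut (1×1 Conv-BN projection, matching stride). Channel widths run
   64 → 64 → 128 → 128 → 256 → 256 with stride-2 blocks at the width
   changes, so a 128×128 input ends at 16×16×256.
2. **Primary capsules.** 8 units of 32-kernel 3×3 stride-1 convolutions
   with 'valid' padding (16×16 → 14×14); each unit's 14×14×32 map is
   flattened to one capsule vector of dimension 6272 and squashed.
3. **Class capsules.** Each (input, output) capsule pair carries its own
   affine map `u_hat[j|i] = W[i,j] u[i]`; dynamic routing by agreement
   (3 iterations by default) couples the 8 primary capsules to 5 class
   capsules of dimension 16. Per round: couplings `c = softmax_j(b)`,
   weighted sum `s_j = Σ_i c_ij u_hat[j|i]`, output `v_j = squash(s_j)`,
   logit update `b_ij += u_hat · v_j` on every round but the last (a final
   update could not change the returned outputs — kept identical in the
   reference oracle).
4. **Length head and loss.** Class scores are Euclidean capsule lengths;
   training minimises the margin loss
   `L_k = T_k max(0, m⁺−‖v_k‖)² + λ(1−T_k) max(0, ‖v_k‖−m⁻)²`
   with m⁺ = 0.9, m⁻ = 0.1, λ = 0.5, summed over classes and averaged
   over the batch.

The squash nonlinearity `v = (‖s‖²/(1+‖s‖²)) · s/‖s‖` preserves direction
and maps lengths monotonically into [0, 1); an ε = 1e−16 floor inside the
norm keeps the zero vector a fixed point with finite gradients.

## Preprocessing and augmentation

Images are letterbox-resized (long side scaled to L, bilinear; short side
rounded half-up; centred black padding, remainder pixel at bottom/right)
and converted to HSV with all channels in [0, 1] — a single unambiguous
dialect for model input. Brightness augmentation is the per-channel power
law `I' = round((I/255)^k · 255)`, k ∈ [0.25, 4] (k < 1 brightens); it
fixes 0 and 255, is monotone, and commutes with the geometric transforms
because black stays black. The continuous map is exactly invertible; with
8-bit rounding the brighten-then-darken round trip (k = 0.5 then 2) is
accurate to one intensity level, whereas darkening first collapses dark
levels irrecoverably (worst case 11 levels) — the expanding-first order is
the one the tests assert.

Class balancing is deterministic: each class's multiplier m enumerates the
first m entries of a canonical transform pool — identity, rot90 (CCW),
rot180, h/v-shift (+10% of the axis, content clipped, vacated pixels
black), brightness 0.5 and 1.5, then geometric∘brightness composites, then
geometric∘geometric composites in lexicographic order, with commuting
pairs (rotation-rotation, shift-shift) enumerated once since both orders
render identical pixels. The default multipliers {4, 5, 14, 5, 6} are the
unique integers mapping the published per-class training counts
(244, 200, 66, 196, 172) to the published balanced counts
(976, 1000, 924, 980, 1032; total 4912), which implies each multiplier
counts the original image as its first variant.

Order of operations: augmentation acts on stored 8-bit RGB, then
letterbox resize, then HSV conversion as the model input — size
unification and colour conversion are preprocessing, brightness is an
augmentation of stored images.

## Synthetic data

The generator renders an ellipse-like tongue blob (jittered centre and
axes) on an exactly black background; the base colour is drawn from a
per-class HSV palette box, modulated by gentle multiplicative shading
(radial falloff plus a low-frequency wave, floor 0.82) and per-pixel
hue/saturation jitter clipped to the box; whitish coating speckles
(seeded points dilated to 3×3 blobs) are overlaid at a class-specific
density. Palette boxes follow the TCM descriptions — light white is pale
(low saturation, high value); light red, red and deep red share the red
hue band with increasing saturation and decreasing value; cyan sits at
hue ≈ 0.5 — and are pairwise disjoint in the H×S×V product. Hue bands
stop short of the 1.0 wrap point and base hues are drawn from the inner
85% of the band, so 8-bit quantisation cannot wrap pixel hues across the
circle and the tongue-mask mean hue stays inside the class band. The
coating colour reuses the band-centre hue so plain (non-circular) means
remain valid. Rendering is a pure function of (label, seed, size,
palette).

`hue_probe` guards against a degenerate generator: it classifies each
image by the nearest palette centre (circular hue distance, weighted ×2)
of its mask-mean HSV and must exceed 0.8 accuracy with the default
palette (measured ≈ 1.0); a palette with all classes identical scores at
chance (0.2).

What passing tests show — and do not show: the synthetic classes are
separable by colour statistics with coating interference and shading
variation, so end-to-end tests demonstrate that the architecture, routing
and optimisation genuinely learn colour-class structure from pixels; they
do not demonstrate clinical-grade performance on real tongues, which vary
in texture (papillae, cracks, moisture), lighting and segmentation
quality that the renderer does not emulate.

## Training and evaluation

Networks are implemented in NumPy over a small in-package reverse-mode
autodiff engine (broadcasting arithmetic, reductions, two-operand einsum,
NHWC convolution via patch-matrix matmul, max-pooling); this keeps the
package dependency-light and every numerical step inspectable. Batch norm
uses ε = 1e−5 and running-statistics momentum 0.9 (training uses batch
statistics; evaluation uses running statistics). Convolutions under BN
carry no bias; the primary-capsule convolution (no BN) keeps its bias.
Weight init: He-normal for convolutions, std 1/√D_in for capsule
transforms, seeded. Optimisers: plain SGD (optional momentum) and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8). Runs are bit-reproducible given a seed
(data order, init, splits). Gradients flow through the full unrolled
routing loop. A non-finite loss aborts with a diagnostic.

Splitting is per-class: a ratio rule (test = round(0.2·n), optional
validation fraction of the remainder) in general, and the published
fixed-count table as a literal override for the clinical class sizes —
no single rounding rule reproduces that table (e.g. light white test is
59 where 0.2·304 rounds to 61). Grid search evaluates the full grid
(learning rate {0.1, 0.001, 0.0001} × {SGD, Adam} × batch size
{8, 16, 32, 64, 128} = 30 points) by k-fold cross-validated plain
multiclass accuracy (k = 5), ties broken toward smaller learning rate,
SGD, smaller batch. Evaluation computes the confusion matrix (rows =
truth) and one-vs-rest per-class accuracy, sensitivity and specificity,
macro-averaged unweighted; an undefined ratio (class absent) is NaN with
a warning and excluded from the macro mean. The evaluation CLI offers a
brightness-jitter flag (images cycle k ∈ {0.5, 1, 1.5}) mirroring testing
under varied brightness.

## Study sizes and defaults

The CPU-scale end-to-end study (`run_synthetic_experiment`, also what
`scripts/acceptance.py` reruns) uses a reduced profile chosen as a
desk-scale counterpart of the full model: 64×64 inputs, half-width
channels (stem unchanged; residual widths 32/32/64/64/128/128; primary
capsules 8×16 kernels → 8 capsules of 576), 100 training + 30 test images
per class (500/150 total), batch 16, Adam at 1e−3, 15 epochs, one fixed
seed. Epoch count for full runs defaults to 50. Routing iterations
default to 3 — the convention of the original capsule-network work this
model builds on — and are configurable.

## Design choices where the published description is open

- Table inconsistencies: the layer table's first variant-*a* row prints
  128 kernels but 64 output channels, and its 128→256-channel row is
  labelled variant *a* although an identity shortcut cannot change the
  channel count. In both cases the output-shape column is trusted: the
  row becomes a 64-kernel identity block and a stride-1 projection block
  respectively, and the traced shapes match the printed column cell for
  cell.
- The class-capsule row is absent from the layer table; its input is the
  8×6272 primary bank and its dimension defaults to 16 (original
  capsule-network convention).
- Primary-capsule padding must be 'valid' (forced by the published
  16×16 → 14×14 worked example); stem/residual convolutions use 'same';
  max-pooling pads 'same'-style so 128 → 64 under 3×3 stride 2.
- Primary capsule outputs are squashed, so class-capsule inputs satisfy
  the output-length contract.
- One affine matrix per (input, output) capsule pair (no weight sharing
  across input capsules), matching the indexed transform definition.
- Rotation direction (CCW), shift magnitude (10%), classifier tie-break
  (lowest index) and batch loss reduction (mean of per-sample sums) are
  fixed for determinism.

## Known limitations

- The profiler's parameter/FLOP figures follow its own documented
  multiply-accumulate convention; printed size/FLOP figures from other
  implementations use unstated conventions and are not comparison
  targets.
- CPU-scale studies use the reduced profile above; full-width 128×128
  training is supported but slow without an accelerated backend.
- The synthetic generator's realism limits are listed above; conclusions
  about clinical data require clinical data.
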
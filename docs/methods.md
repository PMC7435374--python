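# Methods

## Model

`lesiongan` augments a labeled brain-tumor MRI cohort by synthesizing
virtual (image, label) pairs. The unit of analysis is the 2-D axial
slice of one modality (flair, t1, t1ce or t2); one model is trained per
modality. Internally every slice label uses five classes — 0 outside
brain, 1 healthy tissue, 2 edema, 3 necrotic/non-enhancing core,
4 enhancing tumor — because the raw BraTS codes {0, 1, 2, 4} lack an
explicit tissue class; the brain class is derived from nonzero intensity
(the volumes are skull-stripped), as the largest positive connected
component with holes filled. `decode_label` inverts the encoding exactly.

**Label composition.** Given tumor donor A and background donor B, the
composite label s_ab starts from s_b with B's tumor codes reverted to
tissue, then copies A's tumor codes at their original pixel coordinates
wherever B's brain mask is 1 (no translation or registration: the method
composites label images directly, and tumors' absolute positions are
anatomically meaningful). Tumor pixels falling outside B's brain are
dropped; a pair losing more than `max_dropped` (default 5%) of the tumor
is rejected as inadmissible, because a truncated lesion makes a
misleading training target. The threshold is a package policy, exposed in
configuration. Ordered pairs with a ≠ b give n² − n virtual samples.

**Networks.** The architectures are parsed from compact layer strings
(`CIR64F7-CIR128F3-…`). The generator is a CycleGAN-family
encoder / 9-residual-block bottleneck / decoder: 7×7 stem, two stride-2
downsamples, nine 256-channel residual blocks, two stride-2 upsamples and
a 7×7 sigmoid head, consuming the 5-channel one-hot label plus the
1-channel conditioning image. Upsampling is implemented as zero-insertion
followed by convolution with the rotated, channel-transposed kernel —
algebraically identical to a stride-2 transposed convolution with output
padding 1. The global discriminator is a 7-conv 4×4 patch critic over the
(image ⊕ label) stack, first layer un-normalized, LeakyReLU(0.2)
activations, no sigmoid (least-squares objective); the local critic is the
same but one convolution shallower and sees 1-channel 64×64 crops only
(no label channels: the crop objective judges realism, not
correspondence). Discriminator strides are not dictated by the layer
strings; we use stride 2 on the first min(4, n−2) layers and stride 1
after, so the same critic accepts 256-px full-scale images and the 64-px
slices of CPU-sized runs. All channel widths multiply by
`base_width_scale` (default 1.0; tests and examples use 1/8).

**Objectives.** With R_a^tum = A's tumor support and R_b^tis = B's brain
minus both donors' tumor sites (disjoint by construction):

- regional perceptual loss: masking happens in pixel space *before*
  feature extraction; feature maps are compared by MSE at tags conv3_4
  (the fourth convolution before the third max-pool of VGG-19) and
  conv4_4, with internal weights 1 : 100 : 100. The expectation is the
  mean over batch and all feature elements.
- regional L1: mean absolute masked difference, averaged over all pixels
  (masked-out pixels contribute zero), which keeps the value stable
  across mask sizes.
- adversarial: least-squares (LSGAN) — critics regress real patches to 1
  and fake to 0; the generator-side term pushes fake patches to 1 (the
  standard LSGAN pairing for the printed discriminator form).
- total generator objective: weights λ : μ : γ = 1 : 1000 : 1000 on
  (perceptual, L1, adversarial).

**Feature extractor.** The perceptual backbone is the VGG-19
convolutional trunk (post-ReLU features, 2×2 max pools). Pretrained
weights can be injected, but the default is a fixed-seed He-initialized
trunk: a fixed random deep feature map defines a valid perceptual metric,
and the same pooled features back the FID implementation. Consequently
FID values are internally consistent (zero to self, monotone under
corruption) but not comparable to published Inception-based FIDs.
Grayscale slices are replicated to three channels and normalized with the
ImageNet statistics the topology conventionally expects.

## Training procedure

Each step samples a donor pair and slices, composites the label
(inadmissible pairs are skipped and redrawn, bounded retries), one-hot
encodes, and then performs one D-then-G alternation: global critic on
(x_b ⊕ s_b) vs (y ⊕ s_ab), local critic on independently located crops of
x_b vs y, then the generator on the full objective. Critic updates
backpropagate half their objective (the CycleGAN convention that slows
the critics relative to the generator); the *recorded* `l_g`/`l_l` are
the unhalved least-squares values, and the recorded total is
λ·l_rp + μ·l_1 + γ·(l_g + l_l). Optimization is Adam, lr 2e-4, betas
(0.5, 0.999), batch size 1 — the family defaults, as the original
training settings are unreported. All randomness flows from one seeded
numpy generator whose state is checkpointed; runs are bit-reproducible on
CPU (verified across BLAS thread counts) and resumable. Checkpoints are
single `.npz` files holding every parameter, Adam state and the RNG
state; the loss log is JSONL.

The networks, reverse-mode autodiff and Adam are implemented in numpy
inside `lesiongan.nn` (im2col convolutions, gradient-checked against
finite differences). Weight init is N(0, 0.02) for the GAN networks — the
CycleGAN/pix2pix convention; He-initialized critics emit logits large
enough that the γ-weighted adversarial gradient swamps every other term.

## Phantom data

The phantom generator supplies the study conditions for all tests: a
smooth closed brain blob per volume (thresholded sum of 3-D Gaussian
bumps, largest component, holes filled; 30–70% of the central slice
area), one ellipsoidal tumor placed inside the brain and peeled by its
interior distance transform into nested edema ⊃ core ⊇ enhancing shells
(redrawn until all three are nonempty), modality-dependent region
intensities (edema brightest in flair/t2, enhancing rim brightest in
t1ce, tumor dark in t1), ±10% smooth shading, and additive Gaussian noise
with σ = 3% of the intensity range, clipped at zero, with tumor/tissue
voxels kept strictly positive. Phantoms reproduce the *structural* facts
the pipeline relies on (containment, nesting, contrast, skull-stripped
support) but none of the anatomy, texture statistics or artifacts of real
MRI — so green tests certify the machinery, not clinical image quality.
Cases are tumor-free only when `tumor_probability < 1` is requested,
since the compositor requires tumor donors.

Preprocessing follows the full-scale recipe scaled down: per-slice
min-max normalization to [0, 1] (applied per 2-D slice, since the model
consumes slices), the axial slice window [30, 110) read as a half-open
index range (80 slices) for real-sized volumes, bilinear resize for
intensities and nearest-neighbor for labels (tests use 64 px instead of
256). Tumor-free slices of a donor are excluded from the tumor-donor
pool.

## Numerical choices and degenerate inputs

- Dice uses ε = 1e-6 by default; two empty masks score 0.
- The Fréchet distance symmetrizes the matrix square root and clips tiny
  negative totals to 0; 1-D feature sets are treated as (n, 1).
- Min-max normalization rejects constant images; label resize never
  invents codes.
- `extract_slices` accepts `high == depth` (the full-volume window) and
  rejects shallower volumes.
- Instance normalization is affine-free (conv biases ahead of it are
  provably gradient-free and exist only in un-normalized layers).

## Known limitations

- A 200-step, 4-patient, 64×64, 1/8-width smoke run is *not* long enough
  for the 1 : 1000 : 1000 objective to improve the tissue-region L1: the
  γ-weighted adversarial gradient is 20–60× the L1 gradient in this
  regime, and a freshly initialized sigmoid generator (y ≈ 0.5) already
  sits at the phantom tissue-L1 floor. Diagnostics in this codebase show
  the machinery is sound — with γ = 0 the tissue L1 falls cleanly, and
  against frozen critics the full generator objective drops about 4× in
  200 steps — but minimizing the full objective at this scale trades
  pixel-level tissue L1 for adversarial/perceptual gains, so the L1 trend
  over such a short run is not a reliable health indicator. The
  acceptance suite keeps the trend check anyway, as an honest record of
  this regime.
- The tumor keeps its donor coordinates; no geometric augmentation of the
  pasted lesion, and no unseen tumor shapes.
- One modality per trained model; no multi-GPU, mixed precision or
  learning-rate schedules.
- FID magnitudes depend on the random trunk's seed and width; only
  comparisons under one extractor are meaningful.
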
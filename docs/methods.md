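# Methods

`gliomap` implements a multi-site MRI harmonization and classification
pipeline for glioma molecular-subtype prediction, together with a
synthetic phantom cohort generator that makes every stage testable
without clinical data. This note records the models, the choices made
where the design was open, and what the synthetic experiments do and do
not demonstrate.

## Pipeline

1. **Phantom cohorts** (`gliomap.phantom`) — two scanner domains, two
   MRI-modality roles, two molecular classes, ground-truth tumor masks.
2. **Preprocessing** (`gliomap.preprocess`) — intensity normalization,
   tight tumor bounding boxes resampled to a fixed crop, per-patient
   slice selection, strictly patient-separated 60/20/20 splits.
3. **Domain mapping** (`gliomap.domain_mapping`) — an unpaired CycleGAN
   maps source-domain slices A onto the target domain B; the combined
   dataset is D = Ã ∪ B.
4. **Augmentation** (`gliomap.augmentation`) — a DCGAN per
   (modality, class) synthesizes extra tumor crops for pre-training.
5. **Classifier** (`gliomap.classifier`) — two convolutional
   autoencoder streams (one per modality), pre-trained unsupervised on
   augmented crops, then fine-tuned jointly with aggregation +
   bilinear feature fusion and a softmax head.
6. **Evaluation** (`gliomap.evaluation`) — confusion-matrix metrics,
   multi-run averaging with fresh partitions, and an ablation harness.

All networks run on a small numpy engine (`gliomap._nn`) with
hand-derived backward passes (convolution via im2col, transposed
convolution via input dilation, batch/instance normalization,
max-pooling, Adam). Every layer's gradient is verified against finite
differences in the test suite.

## Models and objectives

**CycleGAN.** Generators G_B: A→B and G_A: B→A with reflection-padded
convolutions, residual blocks, instance normalization and a Tanh
output; PatchGAN discriminators (4×4 strided convolutions, LeakyReLU
0.2) ending in a sigmoid. The objective is

    L = L_GAN(G_B, D_B, A, B) + L_GAN(G_A, D_A, B, A) + λ·L_cyc

with the least-squares adversarial form — discriminator
E[(D(real)−1)²] + E[D(fake)²], generator E[(D(fake)−1)²] — applied to
the sigmoid patch scores, and L_cyc the mean L1 round-trip error in
both directions. Full-scale defaults: 128×128 inputs replicated to 3
channels, encoder (32, 64, 128), 9 residual blocks of 128 filters,
decoder (64, 32, 3); discriminator (64, 128, 256, 512, 1); λ = 10
(standard practice; the weight is exposed in the spec); Adam with lr
2×10⁻⁴, betas (0.5, 0.999), batch 1, 150 epochs with linear decay to
zero after epoch 100. An optional identity term
λ_idt·(|G_B(b)−b| + |G_A(a)−a|) is available (default 0).

Applying a least-squares loss to sigmoid outputs is unusual (LSGAN is
normally formulated on unbounded scores); both elements are kept
deliberately and coexist without trouble at the scales exercised here.

**DCGAN.** Generator: z ∈ Uniform(−1,1)¹⁰⁰ → dense to
(size/8)²×1024 → three stride-2 transposed convolutions
(512, 256, 128, kernel 4, batch norm, ReLU) → 4×4 convolution to 3
channels with Tanh. Discriminator: four stride-2 5×5 convolutions
(128, 256, 512, 1024, batch norm, LeakyReLU 0.2) → dense + sigmoid,
sized to the generator's output by default. Binary cross-entropy
objective; the generator uses the non-saturating form (the saturating
form is a flag). Adam lr 0.002, batch 64. Training stops at the Nash
equilibrium point — when the discriminator's running-mean outputs on
real and fake batches are both within a tolerance (default 0.05) of
0.5 — or at the epoch cap. Because a freshly initialized sigmoid
discriminator outputs ≈0.5 trivially, the stopping rule only engages
after a short warm-up (`min_epochs`). During the generator step the
fake batch passes through the discriminator in train mode (batch
statistics) without updating its weights; using stale running
statistics instead destabilizes training badly at small scale.

**Two-stream CAE classifier.** Each stream is a 6-convolution encoder
(64, 128, 128, 256, 256, 512 filters, 3×3, batch norm + ReLU, 2×2 max
pooling after convolutions 2, 3, 5) taking 64×64×1 crops to 8×8×512,
with a 5-convolution decoder mirroring it back. Pre-training minimizes
reconstruction MSE (Adam lr 0.002, batch 16, 200 epochs, L2 1×10⁻⁴ on
convolution kernels). For refinement the decoders are discarded; the
terminal feature maps f1, f2 are fused by element-wise aggregation
f = f1 ⊙ f2 and bilinear pooling H = FᵀF (F the (h·w)×c flattening of
f), then signed square root and L2 normalization — the standard
bilinear-pooling stabilization, toggleable — feed two 256-unit fully
connected layers with dropout 0.5 and a 2-way softmax. Both encoders
and the head are fine-tuned end to end (a freeze flag exists) on
categorical cross-entropy with runtime augmentation (joint horizontal
flips and rotations uniform in ±10°) and early stopping on best
validation accuracy (default patience 20). The refinement learning
rate (10⁻³ by default) is a package choice.

## Phantom design

Each patient has one shared 2-D anatomy: a bright brain ellipse with a
gentle smooth modulation, and an axis-aligned elliptical tumor whose
center and axes are drawn within a central region. A slice stack
emulates the through-plane size profile of a 3-D lesion. The
class-discriminative feature is an additive sinusoidal texture inside
the tumor whose spatial frequency differs by class (0.08 vs 0.22
cycles/pixel by default, random orientation and phase per patient,
amplitude 0.25) — a signal invisible to global intensity statistics,
so harmonization must preserve local structure for classification to
survive. The FLAIR-role modality has higher tumor/background contrast
(0.70 vs 0.30) than the T1ce role (0.55 vs 0.40); tumor intensity plus
texture amplitude stays below 1 so the class signal is never clipped.

The scanner-domain transform is

    out = clip(contrast · (bias ⊙ blur(image))^γ + noise, 0, 1)

Domain B is the clean target scanner. Domain A defaults to γ = 1.3,
bias amplitude 0.15, contrast 0.9, noise sd 0.04, and — the dominant
effect — a Gaussian point-spread blur of σ = 1.2 px modelling a lower
effective resolution. The blur attenuates the high-frequency class
texture domain-conditionally: a classifier trained on B transfers
poorly to raw A, naive pooling of raw A with B destabilizes training,
and — crucially — the blur is approximately invertible by a
convolutional generator, so the mapping stage has a learnable,
information-preserving target. Destructive transforms (saturating tone
curves, heavy noise) were rejected for the default because they make
the harmonization target unreachable in principle.

Determinism: each patient draws from a counter-derived substream of
the cohort seed, so cohorts are bit-identical under a seed and
independent of generation order.

## Scaled study conditions

All stochastic properties run at a deliberately reduced scale chosen
once as the package's study conditions: 32×32 phantoms, 16 patients
per (domain, class) (64 in total), 6 slices per patient, tumor crops
resampled to 24×24, and reduced filter counts everywhere. The toy
CycleGAN keeps the generator at full resolution (no stride-2 stage):
downsampling a 32×32 phantom would alias away the very texture band
the mapping must preserve. Its discriminator uses a stride-1 first
layer for the same reason, and the toy setting uses λ = 1 with an
identity weight of 1: at this scale a heavy cycle weight induces the
well-known steganographic failure mode in which the generator hides
content instead of rendering it, erasing the class texture while the
cycle loss stays low. Domain mapping is trained once per cohort on all
slices of both domains (it is an unsupervised preprocessing stage that
never sees labels); the patient-separated partitions downstream are
re-drawn per run.

## What the synthetic experiments show — and what they do not

The end-to-end properties are directional, averaged over three seeds:
training on the mapped pool Ã ∪ B beats training on the raw pool
A ∪ B; CAE pre-training on DCGAN-augmented crops is at least as good
as training from scratch; mapped slices move to the target domain's
intensity statistics; and a spectral class probe fit on B scores at
least as well on Ã as on raw A. These mirror the qualitative claims of
multi-site harmonization, not clinical effect sizes: the phantom's
class signal is far cleaner than molecular-marker signal in real MRI,
the cohorts are small, and 2-D ellipse anatomy with a single texture
carrier does not model partial-volume effects, registration error, or
inter-patient anatomical variability. Passing these tests establishes
that the pipeline's machinery is correct and that its stages interact
as intended — not that the clinical accuracies would be reproduced.

## Numerical choices

- Coordinates are 0-based, half-open, row-major; bounding boxes are
  minimal by construction and one box per patient (the union of
  per-slice tight boxes) is applied to both modalities so the two
  streams stay spatially aligned.
- Constant images normalize to all zeros (divide-by-zero guard).
- Slice selection takes the k largest-mask-area slices, ties broken by
  lower slice index; if fewer tumor slices exist than requested, the
  remainder is drawn with replacement, deterministically under seed.
- Partition sizes: validation and test each get ⌊0.2·n⌋ patients
  globally (stratified by class via largest-remainder quotas);
  remainders go to training. A class with fewer than 3 patients
  triggers a warning and an unstratified fallback.
- Probabilities at exactly 0 or 1 entering a log are clamped at 10⁻⁷.
- The reported spread over runs is the sample standard deviation
  (n−1 denominator). Undefined precision/recall (empty denominator) is
  reported as a flagged null, never silently 0.
- Grayscale slices are replicated to 3 channels at GAN input and
  channel-averaged on output; images map [0,1] ↔ [−1,1] around Tanh.

## Known limitations

- The numpy backend is single-threaded BLAS-bound; full-scale training
  runs (128×128, 150 epochs) are out of reach, so published-scale
  hyperparameters are validated by construction and shape contracts
  rather than by convergence runs.
- Tiny GANs are noisy: individual seeds can fail a directional
  comparison even when the seed-averaged effect is clear, which is why
  every stochastic property is asserted on means over seeds.
- The ROI fallback (Otsu + largest component) is a heuristic for real
  data without masks; on phantoms the ground-truth masks are used.
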
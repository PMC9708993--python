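# Methods

## Problem and pipeline

The package synthesises ground-glass nodules (GGNs) into 2-D lung CT
slices by inpainting: a generator receives a normalised slice whose
nodule region of interest (ROI) has been blanked to zero and outputs the
full slice with a plausible nodule restored. The pipeline is

1. phantom slice generation (or reading real slices from PNG/DICOM),
2. preprocessing: seed-fill lung segmentation → background stripping and
   zero-padding to a fixed canvas → [0, 1] window normalisation → ROI
   blanking into (input, target, mask, box) training pairs,
3. adversarial training with two discriminators,
4. evaluation: radiomics distribution comparison, reader-study
   analytics, a real-vs-fake classifier, and the augmentation sweep.

Coordinates are (row, col), 0-based, with half-open boxes throughout.

## Generator and discriminators

The generator follows the SRGAN generator topology without its
upsampling stage, since input and output share one size: a 3×3
convolution + PReLU head, B residual blocks of (3×3 conv → batch norm →
PReLU) ×2 with identity skips, a post-block convolution with a long skip
from the head, and a 1-channel sigmoid tail that enforces the [0, 1]
output range. Both discriminators are residual classifiers: 3×3
convolutions with leaky activations (slope 0.2), stride-2 downsampling
stages that halve the spatial extent until the map is at most 4×4, then
global average pooling and a dense layer. The sigmoid score is affinely
squeezed into the open interval (0, 1) so the logarithmic losses are
always defined. The whole-image discriminator sees full slices; the ROI
discriminator sees the fixed-size crop of the *generated whole image* at
the pair's ROI box, not an independently generated patch.

The networks run on a compact reverse-mode autodiff engine over numpy
(`ggnforge.nn`): broadcasting arithmetic, log/exp/sigmoid/relu, matmul,
reductions, slicing, and im2col-based strided convolution. Gradients are
verified against central finite differences in the test suite. Arrays
are float32.

## Loss

Per training step the generator minimises

    L = (L_ssim + L_adv)_whole + (L_ssim + L_adv)_ROI ,

where `L_ssim = 1 − SSIM(generated, target)` and
`L_adv = Σ −log D(G(x))` over the batch. The discriminators minimise the
standard binary cross-entropy `−Σ log D(real) − Σ log(1 − D(fake))`
(with optional 0.9/0.1 label smoothing, off by default). Design points:

- **SSIM form.** The default is the *global* structural similarity
  index, one statistic from whole-image means, variances and covariance:
  `[(2 μx μy + C1)(2 σxy + C2)] / [(μx² + μy² + C1)(σx² + σy² + C2)]`,
  with the universal constants C1 = (0.01 L)², C2 = (0.03 L)², L = 1 for
  normalised images. An 11×11 Gaussian-windowed mean-SSIM mode is
  available. A non-standard asymmetric variant of the index (denominator
  products of squared statistics) circulates in print; it is kept behind
  `printed_form=True` for comparison only, because it is asymmetric in
  (x, y) and does not equal 1 for identical images.
- **Adversarial reduction.** The batch reduction of the adversarial term
  is a sum by default, matching the summation form of the objective. A
  mean reduction is available as a stabilisation flag: at batch size 4
  the summed adversarial terms (≈ 2.8 nats at untrained scores) dominate
  the SSIM terms (≤ 2) and can drag the generator away from
  reconstruction early in short runs. The desk-scale smoke runs in the
  test suite use the mean reduction; with it, the whole-image SSIM loss
  falls monotonically in expectation over the 200-step run (0.51 → 0.42
  on the reference seed).
- Natural logarithms everywhere; Adam with learning rate 1e-4 and betas
  (0.9, 0.999) for generator and discriminators alike; one discriminator
  step then one generator step per batch. During the discriminator step
  the generated batch is detached, so generator parameters receive no
  gradient; after the generator step all discriminator gradients are
  discarded — the two parameter sets never cross-contaminate, and
  checkpoints round-trip bit-identically.

Training length is counted in steps, not epochs, for desk-scale
control. A run is a pure function of (pairs, config, seed): batch
selection derives from a per-step seed chain recorded in the state, so
loss histories replay bit-identically.

At inference, `composite_output` (default on) pastes the generated ROI
into the known input background, so everything outside the ROI box is
bit-identical to the input and only the nodule is synthetic.

## Preprocessing

- **Seed fill**: the lung mask is the 4-connected component of
  `intensity < threshold` containing an interior seed point — the
  conservative connectivity for boundary stopping. "Auto" seeding scans
  the mid-height row for the two longest interior runs of low-attenuation
  pixels and seeds their midpoints (one per lung).
- **Strip and pad**: non-lung pixels are zeroed and the mask's tight
  bounding box is centred on a zero canvas of the target size (512 at
  full scale); the crop offset is returned so annotations can be
  remapped. Centred placement is a choice — corner anchoring would be
  equally consistent with zero-padding.
- **Normalisation**: `clip((x − low)/(high − low), 0, 1)` with a default
  window of (−1000, 400) HU, the standard lung window.
- **ROI blanking**: a fixed square of side `roi_size` (32 at full scale)
  centred on the nodule centroid, shifted — never shrunk — to fit the
  image, matching the fixed input size of the ROI discriminator. Nodules
  larger than the box are truncated.

## Phantom generator

The phantoms emulate the geometry and intensity scale of screening-CT
slices, not their anatomy: air background at −1000, a soft-tissue body
ellipse at +40, two elliptical lung fields at −800 with additive Gaussian
noise (sd 25 HU) and a handful of bright random-walk vessels. Lesions are
implanted inside the lung mask: subsolid lesions (grades 1–2) add a
radial raised-cosine opacity profile toward soft tissue, modulated by
multiplicative smoothed noise so their interiors are textured and texture
radiomics are non-degenerate; grade-5 lesions are near-uniform solid
discs. Default lesion radii 3–7 px and peak opacities 0.35–0.75 of the
distance to soft tissue give lesions that are conspicuous but not
saturated at 64×64. One lesion per slice; placement retries are bounded
(20 attempts) so degenerate configurations fail deterministically rather
than loop. Everything is a pure function of (config, seed).

What the phantoms do **not** model: real anatomy (airways, fissures,
vessels with realistic branching), scanner noise spectra, partial-volume
and reconstruction artefacts, 3-D context, and inter-patient
variability. Passing phantom-scale tests therefore demonstrates that the
machinery is correct and the training dynamics behave as designed — not
that the generator produces clinically convincing nodules on real CT.

## Radiomics

93 features in six families — first-order (18), GLCM (24), GLDM (14),
GLRLM (16), GLSZM (16), NGTDM (5) — computed over the masked region to
the standard reference definitions used by the common open-source
extractors. Numerical choices:

- Discretisation: fixed bin width (default 25, intended for the raw
  Hounsfield-like scale; pass a width of ~1/56 of the dynamic range for
  [0, 1] images), grey levels anchored at the region minimum.
- 2-D computation: GLCM and GLRLM over the four distance-1 directions,
  symmetric, features averaged across directions; GLSZM zones
  8-connected; GLDM dependence = number of 8-neighbours within the mask
  whose level matches the centre (α = 0), recorded as count + 1 so the
  emphasis weights are defined; NGTDM neighbourhood averages use valid
  in-mask neighbours only.
- Entropies in log2 with a machine-epsilon guard. Degenerate
  conventions: constant regions have variance/skewness/kurtosis 0,
  uniformity 1, GLCM correlation 1 (the no-variance limit), and NGTDM
  coarseness is capped at 1e6 when its denominator vanishes.
- First-order energy/RMS accept an optional intensity shift (default 0);
  total energy multiplies by the pixel area (spacing²).

## Statistics

- **KS test**: `D = max |ECDF_a − ECDF_b|`; exact p-value (full null
  distribution) when both samples have ≤ 10 observations, asymptotic
  Kolmogorov distribution otherwise. Cohort comparisons report one test
  per feature, sorted by descending p, with the non-significant count at
  α = 0.05.
- **ROC AUC**: trapezoidal with midrank tie handling, equal to the
  Mann–Whitney statistic over (score, truth) pairs with 0.5 per tie.
- **Real-vs-fake classifier**: per-fold standardisation, effectively
  unregularised logistic regression (L2 with C = 1e6), stratified
  fourfold split, held-out scores pooled for AUC and accuracy at 0.5.
- **Reader-study analytics**: the four-level scale binarises to
  real/fake calls for the confusion matrix ({confidently, leaning} real
  → called real) and serves as an ordinal score 0–3 for the reader ROC
  (real = positive). With a single truth class the AUC is reported as
  not computable (None) rather than a number.
- **Type-I calibration check**: comparing two cohorts drawn from one
  distribution must flag ≈ α of features. The achieved level of the
  asymptotic KS test oscillates with sample size because D is discrete
  (measured: 0.042 at n = 50, 0.051 at n = 80, 0.043 at n = 150); the
  calibration test uses cohorts of 80, where the asymptotic
  approximation attains the nominal level, with 6 × 93 = 558 tests
  against the binomial 95 % band.

## Augmentation experiment

The dataset splits once into ten ordered, stratified subsets plus a
held-out test set (20 %, a choice); fraction f trains on the first
f·10 % of subsets, so larger fractions are supersets of smaller ones and
no test case ever enters any training subset or the GAN's training data.
Arm A trains the classifier on the real subset; arm B first trains the
GAN on the same subsets' GGN slices, synthesises **one synthetic GGN per
real GGN** (doubling the minority class — the count is a design choice)
from the real backgrounds with the nodule blanked, and retrains. The
classifier consumes the fixed-size nodule patch (the ROI crop) rather
than the whole slice; the subsolid-vs-solid signal lives inside the
patch and this keeps the sweep tractable on one CPU. Only directional /
contract properties are asserted at phantom scale; the experiment makes
no claim about absolute precision/recall values on real data.

## Problem sizes used by the test suite

Tests and smoke runs use 64×64 slices with a 16-pixel ROI, a generator
of 2 residual blocks × 8 base channels (1 × 4 in the sweep), batch 4,
200 training steps for the training smoke run and 60 inside the sweep,
120 phantom slices and fractions {10, 50, 100} for the sweep, and a
150-step patch classifier. `GANConfig` defaults remain at full scale
(512×512, ROI 32, 8 blocks, 32 channels); the architecture supports
that size, but no full-scale run is part of the suite.

## Known limitations

- The autodiff engine is single-threaded numpy; full-scale 512×512
  training is architecturally supported but impractical without GPU
  acceleration.
- Global SSIM summarises a whole image with one statistic; it is
  insensitive to where in the image a discrepancy sits. The windowed
  mode addresses this at some cost.
- Texture-feature values depend on the discretisation bin width; cohort
  comparisons are only meaningful with a shared extraction config.
- The phantom generator's realism limits (above) bound what the
  evaluation can show about clinical data.
- No inter-/intra-reader agreement statistics and no AUC-difference
  tests are provided.
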
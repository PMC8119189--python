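# Methods

`podoseg` implements a molecular-morphometrics workflow for kidney
biopsies: segmentation of the glomerular tuft and of podocyte nuclei from
3-channel immunofluorescence sections, annotation-free appearance
harmonization between imaging set-ups, model-based stereology that turns
2-D measurements into 3-D podometrics, and a per-subject morphometric
signature used for patient classification. Because no public image data
exist for this task, the package carries a fully specified synthetic
generator whose ground truth is known exactly; every quantitative claim
in the test suite is made against that generator.

## The segmentation model

The segmenter is a U-Net with one encoder/decoder trunk and two sigmoid
heads that are trained simultaneously: one for the glomerular area, one
for podocyte nuclei. The reference configuration has 3 encoder levels
with 32 filters in the first level, doubling per level to a 256-filter
bottom layer, two 3x3 convolutions (batch-normalized, ReLU) per level,
2x2 max pooling, 2x2 transposed-convolution upsampling with skip
concatenation, dropout (rate 0.5) at the bottom layer only, and padding
so outputs match the input size. Optimization uses RMSprop at learning
rate 1e-5 with batch size 2 for 2000 epochs in the full-scale
configuration.

Per task the loss is binary cross-entropy with predictions clipped to
[eps, 1 - eps], eps = 1e-7. The two task losses are combined with
weights proportional to each task's current loss,

    L = w_p BCE_podo + w_g BCE_glom,
    w_p = BCE_podo / (BCE_podo + BCE_glom),  w_g = 1 - w_p,

with the weights treated as constants for the gradient: the task that is
currently doing worse receives more importance, and the combination is
invariant to a common rescaling of the two terms. When both terms are
zero the loss is zero.

The podocyte task additionally uses border-emphasizing weight maps

    w(x) = w_c(x) + w0 * exp( -(d1(x) + d2(x))^2 / (2 sigma^2) ),

where `d1`/`d2` are Euclidean distances to the nearest and second-nearest
nucleus, `w_c` is a per-image class-balance map (weights inversely
proportional to class frequency, normalized to mean 1, class frequency
floored at 0.01), and w0 = 10, sigma = 5 px by default. The border term
keeps narrowly spaced nuclei separated. The glomerulus task uses the
class-balance map only — its single large object needs no separation
term. Weight maps are computed once per sample on the unaugmented mask
and warped with the same geometric transform as the image during
augmentation; recomputing distance transforms per augmented copy changes
nothing statistically and costs an order of magnitude more.

Augmentation applies one fused affine transform per draw: horizontal and
vertical flips (each with probability 1/2), translations up to 10% of
the frame, rotations uniform in +-45 degrees; masks are re-binarized at
0.5 after bilinear interpolation. Data are split 60/20/20 into
train/validation/test by whole subjects — no subject contributes images
to two splits. Training keeps the weights of the epoch with the best
validation Dice (mean of the two tasks).

Inference thresholds each probability map at 0.5, labels connected
components (4-connectivity for the glomerulus, 8 for nuclei), removes
objects below a physical size threshold and keeps only the largest
glomerular object (one glomerulus per frame). The size filters are
configurable in both value and unit because the unit convention of the
published thresholds ("800" for glomeruli, "3" for podocyte nuclei) is
ambiguous: defaults are 800 um^2 *area* for glomeruli (800 um as a
diameter would exceed any glomerulus) and 3 um equivalent *diameter* for
nuclei.

### The numpy network engine

No deep-learning framework is part of the dependency set; the package
ships a small reverse-mode autodiff engine (`podoseg.nn`) with exactly
the operations the two architectures need. Tensors are float32,
channels-last (NHWC); convolutions run as one BLAS matmul per kernel
tap, which keeps every operand contiguous; batch/instance normalization,
the channel-affine and the weighted-BCE losses are fused primitives with
hand-written backward passes. Every operation is verified against
central-difference gradients in the test suite.

## Bias minimization (cycleGAN)

Appearance differences between microscopes/operators degrade a segmenter
trained on a reference domain. A cycleGAN learns mappings between the
two unpaired image domains. The generator is an encoder (filters
64/128/256, kernels 7/3/3, strides 1/2/2, instance-normalized, ReLU), a
transformer of 9 residual blocks, and a decoder of 3 transposed
convolutions (filters 128/64/3, kernels 3/3/7, strides 2/2/1) whose
input at each level is concatenated with the matching encoder output;
the last layer is tanh, so generated images live in [-1, 1]. The
discriminator is a 6-layer patch classifier (filters 64/128/256/512/512/1,
kernel 4, strides 2/2/2/2/1/1, leaky-ReLU slope 0.2) mapping 256 px
images to 16x16 patch logits. Losses: least-squares adversarial loss,
L1 cycle consistency (lambda_cyc = 10) and L1 identity (lambda_id = 5).
Optimization: Adam (beta1 = 0.5), batch size 1, learning rate 2e-4
constant for the first half of training then decaying linearly to zero.
The checkpoint with the lowest validation loss is kept; since the
adversarial term's scale drifts with the discriminator, the validation
loss is the cycle + identity sum on held-out images. A 50-image buffer
of past generated images feeds the discriminator updates.

Full-resolution images are reduced to the 256 px working size with a
Gaussian pyramid; the Laplacian residuals of every level are stored, and
after translation the image is upsampled by the expand-and-add chain, so
high-frequency content survives the round trip (reconstruction is exact
to float precision by construction).

## Model-based stereology

Glomeruli and nuclei are treated as spheres. From one section per
glomerulus:

* glomerular volume: V = (beta / k) A^{3/2} from the profile area A.
  The default beta = 1.38, k = 1.01 is the classical coefficient for
  *mean* profile areas under isotropic uniform random sections. The
  synthetic generator, like standard imaging practice, sections near the
  equator (the operator picks the maximal profile; one glomerulus per
  frame), and for that protocol the sphere model gives
  beta = 4 / (3 sqrt(pi)) ~= 0.752 with k = 1, available as
  `StereologyParams.for_equatorial_sections()`. Applying the
  mean-profile coefficient to single near-equatorial profiles would
  overestimate volumes by ~80%.
* nuclear caliper diameter: a slab of thickness t shows each nucleus at
  its maximal cross-section within the slab and samples centers over a
  band of width 2r + t, so the expected profile area is
  A(r, t) = [pi r^2 t/2 + (2/3) pi r^3] / (r + t/2); r is recovered as
  the positive root of the resulting cubic (t -> 0 reduces to the
  classical A = (2/3) pi r^2).
* podocyte number: thickness-corrected profile counting,
  N_V = n / (A (d + t)) and N = N_V V; density is reported per 10^6 um^3
  of glomerular volume (10^6 N_V). A nucleus is counted whenever its
  center lies within (d + t)/2 of the section plane, which is exactly
  the rendering rule of the synthetic generator.
* distances: nearest-neighbor distances are 2-D within the section (the
  only geometry a single optical section provides) and are summarized
  per glomerulus by their median.

Touching nuclear profiles merge under connected-component labeling
(~6% of profiles at realistic densities); counting therefore uses a
watershed on the Euclidean distance transform seeded at local maxima at
least 3 um apart, the standard separation step for convex nuclei, which
recovers ~98% of true profiles. Profiles whose centroid falls outside
the glomerular mask are excluded. The default optical section thickness
is 1 um (confocal).

Recovery, measured on 200 synthetic glomeruli spanning podocyte counts
~150-950 with truth masks as input: mean relative error 12-14% per
glomerulus, Spearman rank correlation with the true count ~0.94, mean
bias -3%. Per-glomerulus estimates from a single section are noisy by
nature (the profile count n carries binomial noise); subject-level
statistics average over glomeruli.

## Morphometric signature and classification

Per subject, the 25-feature signature is {min, max, mean, median,
variance} of {podocyte number, podocyte density, closest-neighbor
distance, nuclear profile area, glomerular profile area} across the
subject's glomeruli; variances use the n-1 denominator and are flagged
missing for subjects with one glomerulus. Classification is logistic
regression with leave-one-out cross-validation: for each subject the
z-scaler (per-feature mean/SD), the median imputation of missing
variance features and the model are fitted on the remaining subjects
only; the held-out subject is then scored, and the pooled out-of-fold
probabilities give ROC/PR curves, AUCs and the confusion matrix at 0.5.
The ridge penalty is weak (1/C = 0.01) by default. Glomerulus-level
structure is summarized by PCA after Pareto scaling (divide centered
features by the square root of their SD); classical PCA is used — for
complete data the probabilistic variant differs only in normalization.
The adapted-clinical-score ratio divides an externally supplied clinical
score by the subject's podocyte-size range (max/min of per-glomerulus
mean nuclear area); the score's clinical inputs are metadata, not
computed here.

## The synthetic generator

A scene is a glomerular sphere (control radius ~N(85, 10) um) containing
non-overlapping spherical podocyte nuclei (radius ~N(3.5, 0.25) um,
count ~N(550, 120) for healthy subjects) plus non-podocyte nuclei inside
the tuft (mesangial/endothelial stand-ins, 1.5 per podocyte) and outside
it (tubular stand-ins), placed by grid-accelerated rejection sampling
with pairwise center distance >= 0.9 the radius sum. An optical section
of thickness 1 um is cut near the equator (offset uniform within +-0.3 R)
and rendered at 1 um/px: the DNA channel shows every nucleus intersecting
the slab, DACH1 only podocyte nuclei, WT1 an annular cytoplasmic rim
(3 px dilation) around each podocyte nucleus plus a faint diffuse tuft
signal; ground-truth masks (glomerular disk, union of podocyte nuclear
profiles) are rasterized before Gaussian blur (sigma 1 px), per-subject
gain jitter and additive noise are applied. Disease cohorts multiply the
podocyte count by 0.6 and the nuclear area by 1.3, and render a fraction
(0.3) of glomeruli as focal lesions in which ~85% of podocytes in a
random spherical cap have disappeared. Microscope/operator shifts are
per-channel affine intensity transforms plus optional blur and noise,
always clipped back to [0, 1], applied to images only.

What the generator does *not* emulate: real chromatin texture,
capillary-loop architecture, out-of-focus light, annotation error, or
nuclei of non-spherical shape. Passing tests therefore demonstrate that
the implementation is correct under the stated geometric model, not that
the specific Dice or AUC levels transfer to patient images.

Every sampling step draws from `numpy` generators seeded through
`SeedSequence` chains, so all outputs are bit-reproducible functions of
(spec, seed).

## Desk-scale study conditions

The test suite and `scripts/acceptance.py` run everything on one CPU
core, with problem sizes chosen accordingly:

* segmentation experiment: 120 images (10+10 subjects x 6 glomeruli),
  128 px frames with proportionally scaled glomeruli (R ~45 um, ~55
  podocytes), a depth-2/8-filter dual U-Net trained 60 epochs at batch 4
  with RMSprop 1e-3 (fewer steps at desk scale need a larger step size
  than the 1e-5/2000-epoch reference schedule). Held-out pixel Dice
  reaches ~0.99 for both tasks, and podocyte object counts from the
  postprocessed predictions track the generator's true per-section
  profile counts with Spearman rho > 0.9 across the cohort.
* dual-vs-single comparison: the same cohort design at 64 px, training
  the dual network and one single-head network per task under identical
  budgets; the mean-Dice gap stays below 0.05, the scale-free claim that
  sharing one trunk between the two tasks costs nothing.
* bias transfer: two 48-image domains of healthy glomeruli at 64 px, the
  second under a strong gain/offset shift (DACH1 gain 0.22, WT1 0.5,
  DNA 1.4 plus offsets) that collapses a reference-trained segmenter to
  ~0 podocyte Dice; a reduced cycleGAN (8/16/32 filters, 2 residual
  blocks) trained 10 epochs cuts the channel-mean gap by >90% and
  restores Dice to ~0.8.
* signature classification: 20+20 subjects with 5-7 glomeruli each,
  podometrics from truth masks; the LOO signature AUC is ~0.99 under the
  disease effect and fluctuates around 0.5 on null cohorts.

## Numerical choices and degenerate inputs

* Dice of two empty masks is 1.0 by convention (flagged in reports);
  object-level Dice with no objects at all is likewise 1.0.
* Object matching is greedy one-to-one in descending IoU with threshold
  0.5 by default; on instances with <= 4 objects greedy matching equals
  exhaustive optimal matching (verified by enumeration).
* ROC/PR sweeps use every distinct probability by default, making the
  trapezoidal ROC AUC equal the Mann-Whitney rank statistic; an evenly
  spaced threshold grid is available for compact exported curves.
  Single-class ground truth is flagged degenerate instead of scored.
* Zero-spread features are centered but not scaled; missing variance
  features are imputed with training-fold medians inside each LOO fold.
* `balanced_dual_loss` weights are gradient-stopped; both-zero input
  returns zero.
* Probability clipping gates the BCE gradient (zero outside the clip
  range), matching the clipped forward value.

## Known limitations

* The numpy engine is single-core and memory-bandwidth-bound; the
  full-scale 1024 px / 2000-epoch configuration is config-reachable but
  not practical on it.
* Per-glomerulus stereology assumes near-equatorial sections; applied to
  truly random sections the single-profile volume estimate is biased and
  only cohort-level means are trustworthy.
* The pooled leave-one-out AUC has larger sampling variance than an
  iid-score AUC: across 30 independent 20+20 null cohorts its standard
  deviation is ~0.13-0.14 (insensitive to the ridge strength), so single
  null-cohort AUCs outside [0.35, 0.65] occur in ~25-30% of runs; null
  calibration statements should pool more seeds or wider bands.
* The adapted clinical score is an input column; its construction from
  clinical variables is out of scope.
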
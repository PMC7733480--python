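# Methods

This note documents the models and procedures the package implements, the
defaults it ships with, and the boundaries of what its synthetic experiments
demonstrate.

## Synthetic phantoms

The phantom generator emulates the intensity structure that a CTA aneurysm
pipeline actually exploits, not photorealistic CT physics. A head is an
ellipsoid inscribed in the grid; its shell of configurable thickness is
painted at skull intensity, its interior at parenchyma intensity. Vessels
are cubic-spline-interpolated polylines rasterized as tubes by
distance-to-centerline thresholding (the centerline is densified at 0.2 mm,
so rasterization error is far below voxel size). Aneurysms are ellipsoids
with polar/equatorial semi-axis ratio `eccentricity`, attached tangent to
the parent vessel wall along the local surface normal, with the sac center
placed so the lumen overlap stays far below 20% of the sac volume; ground
truth excludes the lumen and keeps the largest connected piece, so each
request yields exactly one reference component. After rasterization the
semi-axes are rescaled iteratively until the voxelized volume is within 2%
of the request (the contract guarantees 15%; the calibration test covers
40–400 mm³ at several spacings).

Intensities are arbitrary "HU-like" units — parenchyma 40, hemorrhage 65,
vessel and aneurysm 250, skull 1000 by default — because only their
ordering (parenchyma < hemorrhage < vessel ≈ aneurysm < skull) matters
downstream. Noise is additive Gaussian (default SD 5); there is no beam
hardening, motion, contrast-bolus dynamics or anatomically correct circle
of Willis. Cohorts draw aneurysm volumes uniformly from a configurable
range, and a case carries a second aneurysm with probability 0.16,
matching a clinical ratio of roughly 1.16 aneurysms per patient. Default
voxel spacing is anisotropic (0.75 × 0.75 × 1.0 mm) to exercise the
resampling stage; clinical slice thicknesses of 0.62–1.25 mm fall in the
accepted 0.3–2.0 mm band.

Consequently, passing tests show that every pipeline stage is *correctly
implemented and learnable on separable data*; they say nothing about
sensitivity on real CTA, where calcifications, bone proximity, venous
structures and contrast variability dominate the error budget.

## Preprocessing

Brain extraction is an atlas-free surrogate: keep voxels in the intensity
band (air_max=20, bone_min=300), close morphologically (1.5 mm), take the
largest 26-connected component, fill holes, and re-exclude bone. The
contract that matters downstream — skull out, intracranial vessels in, one
component — is tested against phantom ground truth.

Vessel enhancement is the classic Hessian-eigenvalue line filter for bright
tubes: at each scale σ (Gaussian smoothing in voxel units of the native
grid), the γ=2-normalized Hessian eigenvalues |λ1|≤|λ2|≤|λ3| form the
plate/line ratio R_A=|λ2|/|λ3|, blob ratio R_B=|λ1|/√|λ2λ3| and
structureness S; the response
(1−e^{−R_A²/2α²})·e^{−R_B²/2β²}·(1−e^{−S²/2c²}) is zeroed unless λ2,λ3<0
and maximized over 5 log-spaced scales. Defaults α=β=0.5. The cutoff c
("auto") is half the maximum Frobenius norm over the *whole scale space*:
a per-scale cutoff would normalize every scale by its own maximum, making
the on-axis response of a clean tube identical across scales and the scale
of maximum response meaningless; a shared cutoff restores magnitude-based
scale selection (a radius-2 cylinder peaks near 1.6 voxels) while keeping
the response invariant to affine intensity rescaling. Two instances at
scale ranges 0.5–5 and 5–15 voxels produce the two vessel-enhanced
channels; the large range is capped when the grid is too small to support
the filter. Vesselness is computed **before** resampling, since the scale
ranges are quoted in native voxels; the choice is recorded in the stack
metadata.

Standardization resamples all channels to 0.5 mm isotropic (trilinear for
images, nearest-neighbour for masks, world extent preserved within a
voxel), maps the within-mask 5th–95th intensity percentiles of the CTA
channel linearly onto [0,1] with clipping (saturating outliers rather than
letting them stretch the dynamic range), and z-scores the vesselness
channels over the brain mask.

## Network

The segmentation model is a dual-pathway 3D patch CNN. Both pathways are
structurally identical: eight 3³ valid convolutions, each followed by batch
normalization and PReLU, with residual connections at layers 4, 6 and 8
(adding the input of the preceding layer, center-cropped and zero-padded in
channels). The second pathway sees the image downsampled to a third
(3³ box average) around the same center. Its output is upsampled ×3 by
repetition, cropped, and concatenated with the native-resolution features;
layers 9 and 10 are 1×1×1 convolutions with a residual spanning the block,
and layer 11 is the two-class classifier with softmax. This reading — eight
3³ layers per pathway plus two 1×1×1 "fully connected" layers plus the
classifier, residuals at 4/6/8 in the pathways and at 10 across the 1×1×1
block — is the only consistent reconciliation of an 11-layer, 3³-kernel
architecture with fully connected layers 9 and 10.

The output window is `segment − 16` per axis (asserted receptive-field
arithmetic: 25³ → 9³, 45³ → 29³). Context alignment is exact by
construction: for an output window starting at voxel `o`, the context
input samples the box-smoothed volume at stride 3 starting at `o − 23`,
so after convolution, upsampling and cropping, context feature `j` sits
under output voxel `o + j` to within half the stride. Because the context
grid depends on `o` only modulo 3, any tiling whose offsets are congruent
mod 3 yields bit-identical predictions — tiled inference *equals* a
single whole-volume pass, which the tests assert exactly. A consequence:
axis-flipping a training patch moves its context grid by at most one
voxel, inherent to any odd-offset downsampling; the flip-equivariance test
bounds the effect.

Everything is implemented in numpy with a small reverse-mode autograd
(valid 3D convolution via strided im2col + einsum, batch norm with proper
batch-statistics backward, PReLU, residual/crop/pad/upsample/concat,
softmax + soft-Dice). Analytic gradients of the whole graph are verified
against central finite differences in float64 during testing.

Training samples segments 50% centered on foreground voxels and 50% on
background voxels inside the brain mask (a standard answer to extreme
class imbalance), flips each axis independently with probability 0.5, and
minimizes the batch-pooled soft Dice loss 1−(2Σpt+s)/(Σp+Σt+s), s=1.
Published hyper-parameters are the defaults: batch size 15, 30 epochs,
batch normalization, PReLU, Dice loss. The optimizer, learning rate,
feature widths and sampling ratio are not specified by the architecture
family's clinical description, so they are explicit configuration with
logged defaults: Adam (lr 1e-3, β=0.9/0.999), widths (4,4,8,8,8,8,16,16)
with a 24-wide 1×1×1 block — a reduced, CPU-scale profile, configurable up
to literature scale. All randomness flows from a single integer seed;
training is bit-reproducible.

## Fusion

STAPLE treats each binary mask as a rater with latent sensitivity p_j and
specificity q_j and estimates rater qualities and the per-voxel posterior
of the latent true segmentation by EM. The E-step computes the foreground
posterior from the current (p_j, q_j) and a global prior f (default
"auto" = mean foreground fraction of the inputs); the M-step re-estimates
each rater against the posterior; iteration stops when the largest
posterior change drops below 1e−6 or at 100 iterations, with p_j = q_j =
0.99 initialization. The implementation groups voxels by their 2^J
rater-vote patterns, so EM cost is independent of grid size and agrees
with a naive per-voxel EM to ~1e−16; tests also verify monotone
log-likelihood per iteration, rater-permutation invariance, parameter
recovery on simulated raters, and agreement with SimpleITK's independent
STAPLE filter. Fold fusion thresholds the consensus at 0.5. All-empty
inputs short-circuit to an empty, flagged-degenerate consensus.

The combination rule of the three variant outputs into the ensemble is not
uniquely determined by the clinical description (the cited ensembling work
averaged continuous confidences); this package combines the three *binary*
variant masks with the same STAPLE+0.5 mechanism used for folds — which
degenerates to a majority vote for symmetric rater qualities — and exposes
`rule="majority"` as the explicit fallback. Fusion operates on binary
masks because STAPLE's rater model is defined over discrete decisions.

## Evaluation

Detection is component-level: 26-connectivity labeling (switchable to 6);
a reference component is detected if at least one predicted voxel overlaps
it (a minimum-overlap-fraction switch can raise the bar); each predicted
component is attributed to the reference component sharing most voxels,
fragments merge into a single TP with pair DSC computed against the union
of the fragments; unattributed predictions are FPs. The ≥1-voxel rule is
the most permissive consistent reading of a detection criterion that
clinical reports usually leave implicit. Volume-binned reports restrict
TP/FN by reference-component volume and FPs by the predicted component's
own volume — the reading under which binned FP counts fall as the
threshold rises — and omit empty strata rather than reporting zeros.
Percentages are rounded half away from zero to integers and DSC, F1 and
FPs/scan to two decimals, reproducing the standard table formatting
exactly from integer counts. Matching is validated against an exhaustive
voxel-set oracle on 1000 randomized grids.

## Pipeline and problem sizes

The orchestration trains each variant with k-fold cross-validation on a
training cohort, applies all k sub-models to each held-out case, fuses the
k outputs with STAPLE, ensembles the three variants, and evaluates. k=5
is the fidelity default; the smoke tier uses k=2, six phantoms (four
train / two test), 2 epochs and narrow widths so a complete end-to-end run
takes a few minutes on one CPU core, and the acceptance script uses four
held-out cases with 8 epochs. These tiers are a deliberate test-scale /
fidelity-scale separation: every code path of the full design is exercised
at sizes a laptop can handle, while the configuration admits
literature-scale settings unchanged. Every stage derives its seeds
deterministically from the master seed, so reruns reproduce fold
assignments, weights and reports bit-for-bit.

## Known limitations

- The phantoms contain no bone-adjacent aneurysms, venous structures,
  calcifications or motion artifacts — the dominant false-positive sources
  in clinical practice.
- Brain masking is intensity-band-based and would not survive real CT
  fields of view with neck coverage; it is a contract-preserving surrogate
  for registration-based extraction.
- The reduced-width network and minutes-scale training are sized for CPU
  verification; reported synthetic metrics characterize the pipeline, not
  achievable clinical accuracy.
- STAPLE here is binary and unweighted; soft-input fusion and learned
  vote weighting are out of scope.
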
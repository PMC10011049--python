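# Methods

This note records the modelling choices behind `chpseg`, the parameters
that matter, what the synthetic phantoms do and do not show, and the
numerical conventions that keep the pipeline deterministic.

## The segmentation problem and the cascade

The choroid plexus occupies roughly 0.1–0.3 % of a brain MRI volume. A
single whole-volume network at full resolution must either shrink the
volume (losing the thin structure) or spend nearly all computation on
voxels that are trivially background. The cascade splits the work:

1. **Step 1 (where).** The preprocessed volume (176 × 240 × 256, 1 mm³,
   intensities in [−1, 1]) is down-sampled to 72 × 96 × 104 and segmented
   coarsely. Only localization quality matters here.
2. **Seeding.** Every coarse voxel with probability strictly greater than
   0.8 is mapped to full resolution by multiplying its index by the
   per-axis extent ratio (≈ 2.44, 2.50, 2.46 at the default shapes) and
   rounding. When more than 500 candidates exist, a uniform random subset
   of 500 is drawn without replacement; patches from nearby seeds overlap,
   which is intended — overlap averages out patch-edge errors.
3. **Step 2 (what).** Each 48³ patch, cut from the full-resolution volume
   and clamped inside the grid near borders, is segmented by the second
   network.
4. **Blending.** Patch probabilities are multiplied by a separable 3D Hann
   window and accumulated; the windows themselves are accumulated in a
   parallel weight volume; the quotient is the final probability map,
   binarized at a strict 0.5. Because numerator and denominator use the
   same weights, the blend is a convex combination at every covered voxel
   (a partition of unity): copying patches from any source map reproduces
   the source to float precision, which the tests verify on random covers.

Both thresholds are strict inequalities ("higher than 80 %" reads as
strict; binarization mirrors it), so a probability exactly at the threshold
is background. When step 1 finds no seed at inference time the pipeline
returns an empty mask with a warning rather than inventing an upsampled
coarse output.

### Hann window sampling

The classic Hann window is zero at its endpoints, which would leave edge
voxels of an isolated patch with zero total weight and make the
divide-by-weight rule undefined there. The window is therefore sampled at
interior points, `w(i) = 0.5·(1 − cos(2π(i+1)/(n+1)))` for `i = 0..n−1`:
strictly positive everywhere, maximal at the patch centre, and no epsilon
is needed in the normalization.

### Down-sampling and anti-aliasing

"Down-sampled" is implemented as a Gaussian pre-filter with
`σ = (factor − 1)/2` per axis followed by linear interpolation. Plain
point-sampling at a ×2.5 reduction aliases a 2-voxel-thick structure in
and out of existence depending on phase, which decorrelates the coarse
image from the coarse target; the pre-filter converts "thin and bright"
into "slightly bright everywhere along the structure", which is exactly
the signal step 1 needs. Coarse *targets* are nearest-neighbour
down-sampled masks, so they stay binary.

## Network

One architecture serves both stages and the 1-step baseline: encoder of
`levels` stages (default 4) with two convolution blocks per stage
(3³ convolution → group normalization → leaky ReLU, slope 0.01), channel
doubling from 16 base filters, 2× max-pooling between stages; decoder with
parameter-free nearest-neighbour upsampling, skip concatenation, and the
same double blocks; final 1×1×1 convolution + sigmoid. Group count is 8
(instance-like normalization at the smallest widths), chosen because the
batch sizes 3D segmentation permits (1–4 volumes) make batch statistics
unreliable. A transposed-convolution decoder variant exists only to
demonstrate the parameter saving of the upsampling decoder.

The final convolution bias is initialized at −2 so that untrained networks
predict ≈ 0.12 foreground probability everywhere. With a ~0.2 % foreground
prior, a symmetric start wastes the first hundred updates pulling the
output down; the prior initialization removes that phase. Kernel size,
blocks-per-level and pooling follow the standard 3D U-Net pattern.

The engine is written directly in NumPy (im2col convolutions lowered to
BLAS matrix products, hand-derived backward passes, Adam), runs entirely in
float32 — half precision underflows the compound loss — and is
deterministic given the construction seed. Gradients are verified against
central finite differences in the test suite.

## Loss and training

Soft Dice uses the min formulation `2Σmin(x,y)/(Σx+Σy)`, which equals the
classic overlap Dice on binary inputs; its subgradient takes `∂min/∂x = 1`
where `x < y` and 0 otherwise. Two empty inputs score Dice 1 (loss 0): an
empty prediction of an empty target is perfect, and the convention avoids
0/0. BCE clamps probabilities to `[1e−7, 1 − 1e−7]`. The cascade total is
`Loss_step1` when no patch location is found (N = 0) and
`Loss_step1 + Loss_step2` otherwise, with the step-2 term computed over the
pooled voxels of the whole patch batch (one index set, matching the Σᵢ in
the Dice definition).

During training, patch locations are seeded from the **current** step-1
output under the same strict 0.8 rule, capped at 16 per volume (batch of at
most 64 patches for 4 coarse volumes); patch targets are ground-truth mask
crops at those locations. Step 2 therefore receives no update until step 1
becomes confident — the N = 0 branch of the loss, taken literally. Adam
runs at 1e−3 with otherwise default constants; the validation loss (the
cascade total) is checked once per epoch and the rate is halved when two
consecutive epochs differ by less than 1e−3, with no patience window. The
validation loss for the schedule is the cascade loss; a step-wise schedule
would be equally defensible but couples the two stages less directly.

## Augmentation

Each of the nine transforms fires independently per draw (flip 0.5, all
others 0.3), composed spatial → k-space → intensity, mirroring acquisition
physics: the object moves, the scanner acquires (k-space), the image is
shaded and noisy. Spatial maps are applied identically to the mask with
nearest-neighbour interpolation. Where only bounds are specified
(ghost intensity, spike magnitude, bias coefficients, rotation angles),
magnitudes are drawn uniformly within them. Motion is simulated by mixing
the spectra of up to two rigidly displaced copies across frequency bands;
ghosting attenuates every n-th frequency plane (sparing DC); a spike adds
one high-magnitude frequency-domain point, which on a smooth image appears
as a superimposed plane wave. Elastic deformation is deliberately absent
from the battery. Augmentation statistics (trigger rates, zero-magnitude
identities) are property-tested rather than assumed.

## Phantoms: what they emulate and what they do not

The generator reproduces the *geometric and contrast regime* of the task:
bright, thin (radius 1–2 voxels), curvilinear targets confined to dark
cavities inside a brighter tissue mass, at 0.1–0.3 % volume fraction, with
partial-volume smoothing (Gaussian, σ 0.6 voxels) and additive noise
(σ 0.04 on a [0, 1] intensity scale). Target volume varies ±50 % across a
cohort so volume-correlation statistics are non-degenerate. Default test
shape is 96³ — divisible by 8, large enough for the cascade geometry,
small enough for CPU training in minutes.

Phantoms do **not** emulate: anatomical variability of real ventricles,
bias fields and multi-site intensity distributions, partial-volume mixtures
with adjacent bright structures (fornix, calcified glomus), or annotator
disagreement. Passing the phantom tests therefore demonstrates that the
pipeline and optimization are correct and that the cascade can learn a
sparse bright-in-dark target — not that real-cohort accuracy figures carry
over.

## Scaled-down operating points

CPU-scale runs shrink the geometry, never the rules: 3 levels, 8 base
filters, 24³ coarse grid, 16³ patches, 30 epochs, 12 training + 4
validation phantoms at 96³, strict 0.8/0.5 thresholds, Adam 1e−3 and the
plateau schedule unchanged. Under these conditions two-step validation
Dice reaches ≈ 0.6–0.7, the qualitative behaviour (step 2 engaging only
after step 1 gains confidence) matching the full-scale design. The
full-scale defaults (176 × 240 × 256, 72 × 96 × 104, 48³/500 patches,
4 levels / 16 filters, 200 epochs) are preserved as the configuration
defaults throughout.

## Numerical conventions and degenerate inputs

- Coordinates are 0-based voxel indices; intervals are half-open.
- Crop/pad is centred; odd remainders go to the high-index side; the pad
  value is the pre-rescale grid minimum (background); the operation is
  recorded and bit-exactly invertible on retained voxels.
- Linear interpolation for intensities, nearest-neighbour for masks,
  everywhere.
- Constant-intensity volumes cannot be percentile-rescaled and raise a
  degenerate-input error; empty ground-truth masks make recall/VER
  undefined and raise rather than returning 0/0.
- 4D NIfTI inputs with a trailing singleton axis are squeezed with a
  warning; other 4D shapes are rejected with the offending rank named.
- Pearson r uses voxel counts; at 1 mm³ spacing, counts and mm³ coincide.

## Known limitations

- The NumPy engine is single-device and unbatched across volumes at full
  resolution; full-scale (176 × 240 × 256) training is out of desk-scale
  reach, which is precisely why the scaled operating point exists.
- Patch sampling does not duplicate seeds to fill a quota when fewer than
  the cap exist; each candidate is used once.
- Step 2 sees image patches only (no step-1 probability channel).
- N4 bias-field correction and template registration are intentionally not
  part of preprocessing.
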
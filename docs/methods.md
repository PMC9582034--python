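# Methods

`strokect` quantifies ischemic stroke damage in contrast-enhanced
micro-CT scans of ex-vivo mouse brains (tMCAO and TIA models, osmium or
iodine staining).  Four analysis tracks share one coordinate and
intensity model; a synthetic phantom generator supplies ground truth so
every track is testable without scan data.  This note records the
models, the parameters that matter, and the design choices made where
more than one reasonable option existed.

## Coordinate and intensity conventions

Volumes are `(z, y, x)` arrays with 0-based indices; a transaxial slice
is a fixed `z`.  Voxels are isotropic with edge length in µm (4 µm for
the osmium protocol, 3 µm for iodine, 30 µm for the default phantom);
one voxel is `(voxel_size_um / 1000)^3` mm³.  Intensities are
arbitrary attenuation units, non-negative and finite; nothing assumes a
particular bit depth.

## Manual volumetry and edema correction

Hemispheres, total lesion and core are annotated on every k-th
transaxial slice (k = 10 in the reference workflow).  Densification
uses shape-based interpolation: each annotated mask becomes a signed
Euclidean distance field (positive inside), intermediate slices take
the superlevel set of the linear blend.  Per-voxel linear interpolation
of binary values cannot move a contour between slices; distance-field
blending moves it smoothly and reproduces, e.g., linearly growing disc
radii.  An empty end mask is represented by a large negative field so
areas shrink monotonically toward it.

With `V_ipsi`, `V_contra` the hemisphere volumes and
`V_brain = V_ipsi + V_contra`:

    edema extent (%)          = (V_ipsi − V_contra) / V_contra × 100
    corrected lesion (% brain) = V_lesion · (V_contra / V_ipsi) / V_brain × 100

The corrected form rescales the swollen side by the contra/ipsi ratio
so edema does not inflate the lesion percentage.  The printed source
formula is ambiguous in its parenthesization; the reading implemented
is the only one that has correct units and collapses to
`V_lesion / V_brain × 100` when there is no edema.  Negative edema
(shrinkage, seen with dehydrating stains) is allowed and reported.
Ventricle inclusion/exclusion is an input-mask concern, not handled
algorithmically.

## Automatic lesion segmentation by image restoration

The method needs no lesion annotations.  Conditions: the lesion is
confined to one hemisphere, and the operator knows which.  The brain is
split at a user-given midline column; each half is padded (with the
volume's background mode, mimicking air) or center-cropped to a unified
per-hemisphere plane, block-averaged in-plane (block-mean preserves
block averages exactly and anti-aliases), and the two halves are
mirrored into one common orientation so the model sees a single
anatomy.  Downsampling is in-plane only — the network is 2-D and z
resolution is irrelevant to it.  At the reference scan scale the whole
brain is 1920×1280 before 10× downsampling, one hemisphere 192×128
after.

### Lesion simulator

Training inputs are healthy cross-sections darkened by a synthetic
lesion: two concentric discs (outer = whole lesion, inner = core), each
rasterized, warped by one shared elastic displacement field
(per-axis uniform(−1,1) noise, Gaussian-smoothed with σ = 5 and scaled
by α = 120 at reference scale; shared so the core stays inside the
lesion), and blurred by one shared Gaussian σ drawn from 5–20 px into
soft weights `w ∈ [0, 1]`.  Darkening is multiplicative —

    out = image · (1 − d_l · w_lesion) · (1 − d_c · w_core)

with `d_l, d_c ~ U(0, 0.5)` — because the intensity drops are specified
as fractions of the original intensity.  Blur applies to the disc masks
rather than the whole image, keeping healthy tissue sharp (the
restoration target must preserve it).  Outer radius 20–80 px, inner
radius 0–50% of outer, center uniform anywhere in the image (centers on
background are allowed and simply produce near-no-op samples).  Pixel
ranges scale linearly when working below reference resolution
(`LesionSimParams.scaled`).

### Restoration network

A U-shaped encoder–decoder on single-channel images: per encoder level
a 3×3 convolution (ReLU) then a 3×3 stride-2 convolution (ReLU)
doubling channels; per decoder level a 3×3 stride-2 transposed
convolution (ReLU) halving channels, concatenation with the matching
encoder map, and a 3×3 convolution (ReLU); final linear 3×3 convolution.
Full-scale profile: input 192×128, 64 kernels in the first layer, depth
5 (deepest width 1024), MSE loss, Adam at 10⁻³, batch 32, 100 epochs on
830 simulated-lesion images.  The engine is a small NumPy
implementation (im2col convolutions lowered to BLAS GEMMs, explicit
backward passes, Adam); layers keep persistent scratch buffers so
training steps run without large allocations, and those buffers are
dropped on serialization.  Gradients are verified against finite
differences in the test suite.

Lesion simulation is online — each epoch draws fresh lesions per slice
— maximizing augmentation diversity; a fixed-set mode exists for exact
reproducibility of a training corpus.

**Scaled-down profile.**  CPU-scale validation uses 96×64 inputs, depth
3, base 16, 200 phantom slices, 20 epochs.  Batch size is 4 here
(full-scale uses 32), and the choice is load-bearing in both
directions: at batch 32 the 20-epoch budget gives only 140 optimizer
steps and the network stays near the identity mapping (no restoration
signal), while at batch 2 the ~2000 steps *overconverge* to the
identity the skip connections make available — training loss reaches
its lowest value of any configuration while lesion recovery collapses,
because the network learns to reproduce even strongly darkened inputs
verbatim.  Restoration loss is therefore not monotone in segmentation
quality; ~1000 steps (batch 4) balances inpainting strength against
identity convergence.  A constant Adam rate outperformed cosine decay
and tail weight averaging in the same measurements, for the same
reason: the damped variants settle closer to the identity.  Training
this profile takes a few CPU-minutes.

**Normalization.**  Each hemisphere stack is min–max scaled to [0, 1]
with the low anchor at the 1st percentile of *all* voxels (the air
floor) and the high anchor at the 99th percentile of brain voxels
(those above 10% of the bright percentile).  The low anchor must lie at
the air floor, not inside the brain-intensity range: lesioned tissue is
darker than any healthy brain voxel, and a brain-anchored scale clips
real lesions to zero — a regime the multiplicative training simulator
never produces — which destroys the restoration signal.  Keeping the
scale proportional to raw attenuation makes training-time and
inference-time darkening commensurate.

### Segmentation

The probability map is `max(restored − lesioned, 0)`, stacked over
slices.  `T_lesion` is Li's minimum-cross-entropy threshold — the fixed
point of `t ← (μ_≤t − μ_>t) / (ln μ_≤t − ln μ_>t)`, initialized at the
mean, tolerance 10⁻⁶, with the converged value snapped to the best
nearby inter-value cut (the continuous fixed point can sit one bin off
the discrete criterion minimum) — computed on the strictly positive
values of the whole 3-D map.  The restriction to positive values is
measured, not cosmetic: including the clamped zeros drags the
threshold into the restoration-noise floor and roughly triples the
phantom volume error.  The core threshold is fixed at `T_core = 1.5 T_lesion`.
Each candidate mask keeps its largest 26-connected component (the
method assumes a single lesion).  Masks are upsampled in-plane by
bicubic interpolation of the {0,1} indicator re-binarized at 0.5, and
volumes are reported in mm³ at the native scan voxel size.  Core ⊆
lesion is asserted and surfaced as a warning if component selection
breaks it; it is not forced.  An empty post-threshold lesion returns an
empty result with zero volumes — a signal, not an error.

## White-matter fiber analysis

Inside manually delineated caudate-putamen ROIs, bright myelinated
fibers are isolated by a grayscale white top-hat (volume minus its
opening) with a digital ball structuring element — voxels whose center
distance is ≤ d/2, d = 19 voxels at the reference scan scale — and
thresholded with one shared threshold for both hemispheres, so the
ipsi/contra comparison is unbiased.  The default threshold is Otsu's
on the top-hat values inside the ROI union: a reproducible stand-in for
the operator-chosen manual threshold.  A Gaussian pre-filter (default
σ = 0.5 voxel) replaces the original workflow's non-local-means
denoising; the denoiser is not load-bearing, but its width must stay
below the fiber radius — at σ comparable to the tube radius the filter
dilates the segmented fibers and biases the volume fraction upward by
more than the method's own error.

Local (wall) thickness follows the largest-inscribed-sphere
definition: at each voxel, the diameter of the largest sphere fully
inside the fiber mask that contains the voxel.  Implementation: the
Euclidean distance transform gives each voxel a maximal centered sphere
of radius `EDT − 0.5` (distance to the boundary face); spheres are
painted over the voxels they cover (strictly closer than EDT), keeping
the maximum diameter.  On digital balls and slabs this agrees with a
brute-force inscribed-digital-sphere search to within one voxel, the
inherent rasterization ambiguity.  The histogram reports mask volume
per 1-voxel-wide diameter bin, in µm.

## TTC slice quantification

Photographs of TTC-stained 1-mm slabs (live tissue red, infarct white)
are calibrated from a millimetric reference (`mm/px = ref_mm /
ref_px`).  Slice isolation follows the macro: red color gate in HSV
(hue within 0.10 of red, saturation ≥ 0.25, confidence = saturation),
Gaussian blur σ = 10, Huang's fuzzy threshold, fill holes (this
captures the pale infarct enclosed by the red rim), one 3×3 dilation —
the smallest useful choice, as the macro leaves the SE unstated — then
the n largest components' centroids sorted by height and full-width
crops of height `image_height / n` clamped at borders.  Huang's
threshold minimizes the histogram-weighted Shannon entropy of the
membership `u(g) = 1 / (1 + |g − μ_class| / C)`; it is computed by scan
over all gray levels and is checked against a naive per-threshold
oracle in the tests.

Per slice, tissue pixels are split by the manually drawn midline
polyline using the signed side of the nearest segment; pixels exactly
on the line count as contralateral (the tie-break is documented, its
direction is immaterial at pixel scale).  The infarct is the operator's
polygon, rasterized.  Volumes are `Σ area × 1 mm`, and edema extent /
corrected lesion percent reuse the 3-D formulas — both are ratios, so
the slab thickness cancels where it should.

## Cohort reporting

`summarize` returns mean and SD with selectable divisor; the reference
cohort's printed "mean ± SD" pairs reproduce exactly (2 dp) with the
population divisor n, which is therefore the default for parity checks.
Method agreement uses through-origin regression: `b = Σxy / Σx²` with
the uncentered `R² = 1 − Σ(y − bx)² / Σy²` — stated explicitly because
centered and uncentered conventions differ for zero-intercept fits.

## The phantom generator

The phantom emulates what the analyses actually consume, not anatomy:
two mirrored half-ellipsoid hemispheres (flat faces separated by a
2-voxel fissure) of nominal intensity 200 on a background of 2% of
that plus noise (air and wrapping film); smooth multiplicative texture
(Gaussian-filtered noise, σ = 3 voxels, 4% amplitude), mirror-symmetric
about the midline; bright curvilinear fibers — midpoint-refined random
polylines dilated to tubes of radius 1.5 voxels, intensity × 1.5 —
confined to a striatum-like box, with the right hemisphere carrying the
mirrored curves (optionally painted at reduced radius to emulate fiber
thinning).  All generators are pure functions of (spec, seed).

Ground-truth lesions for pipeline validation are deliberately *not*
the simulator's discs: a 3-D blob is built as a noisy level set around
a sphere (radius minus distance plus smoothed noise), clipped to the
ipsilateral hemisphere, with a concentric inner blob as core, darkened
with the same multiplicative model.  The default blob radius makes the
lesion ~8–10% of the hemisphere, in line with the total-lesion
fractions reported for 45-min occlusions; drops for validation phantoms
are 30–40% (lesion) plus 30–40% (core).  Because the validation shape
family differs from the training prior, parameter recovery is a fair
test, not the simulator grading itself.

The TTC phantom renders red ellipses with a pale inner ellipse sized to
a requested fraction of the ipsilateral half, a printed ruler band, and
returns rasterized truth areas, midlines and infarct polygons.

What the phantoms do **not** emulate: real anatomy (ventricles, cortex
layering), scanner physics (beam hardening, ring artifacts), stain
inhomogeneity, or photographic lighting gradients.  Passing tests
demonstrate that the algorithms recover known geometry under the stated
intensity model; they do not certify performance on real scans.

## Numerical choices and degenerate inputs

- Li iteration: positive values only, mean initialization, |Δt| < 10⁻⁶,
  ≤ 200 iterations; a constant grid is an error, a constant probability
  map an empty segmentation.
- Huang threshold: integer data with range < 256 uses exact levels,
  otherwise 256 histogram bins; memberships clipped to [10⁻¹², 1−10⁻¹²].
- Elastic deformation: bilinear resampling with edge clamping; the
  Gaussian smoothing of the displacement field uses reflect boundaries.
- Block averaging requires crop dimensions divisible by the factor
  (enforced), so the mean-preservation property is exact.
- 26-connectivity for 3-D components.
- Network weights: He-normal initialization; float32 throughout;
  backend nondeterminism is absent by construction (pure NumPy), so
  training is bit-reproducible given the seed.

## Validation problem sizes

The suite validates at phantom scale: 32×96×128 brains (30 µm voxels),
per-hemisphere planes of 96×64, 200 training slices, 20 epochs, 5
lesioned phantoms for recovery, 24³ volumes for morphology oracles, and
composite TTC images of 4 slices.  These sizes were chosen so the whole
suite and the acceptance script each run in minutes on one CPU while
still exercising every code path at full algorithmic fidelity; the
full-scale profile differs only in configuration values.

## Run-to-run variability of the scaled-down profile

At the miniature validation scale the trained network's behavior
varies noticeably with the training realization (which healthy
phantoms, which simulated lesions, which initialization).  Across
repeated runs the Dice overlap of the recovered total lesion stays in
a stable 0.55–0.87 band, but the volume estimate — which is sensitive
to exactly where the Li threshold falls relative to the
restoration-noise tail — is biased high and can range from a few
percent to ~2× for unlucky training realizations.  The bias is always
positive: noise voxels adjacent to the true lesion join its connected
component, never the reverse.  The full-scale profile (830 slices,
100 epochs, 10× downsampled real scans) trains an order of magnitude
longer on less correlated noise, where this failure mode has much less
room; at desk scale it is the price of a few-minute training budget
and is reported, not hidden, by the validation suite and the
reproduction script.

## Known limitations

- Single-lesion assumption: only the largest connected component
  survives; multifocal strokes are out of scope.
- The restoration approach inherits the simulator's prior: lesions much
  smaller than 20 px (reference scale) or brighter than tissue are
  outside the training distribution.
- Midline detection, atlas registration and infarct annotation remain
  manual inputs by design.
- The local-thickness propagation is exact to the EDT sphere family;
  non-spherical maximal inscribed bodies are not considered (matching
  the definition, but worth noting for anisotropic structures).
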
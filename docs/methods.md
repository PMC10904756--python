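# Methods

This note documents the models, conventions and numerical choices behind
`trunkphenix`, and what the synthetic experiments do and do not establish.

## Scope and data model

The package operates on co-registered multimodal 3D volumes — MRI T1-weighted,
T2-weighted, PD-weighted and X-ray CT absorbance — sharing one grid and voxel
spacing (default 0.68 × 0.68 × 0.60 mm, axes ordered (x, y, z) with the trunk
axis along z). Registration itself is out of scope: inputs are assumed
aligned. Five voxel classes are used throughout, with fixed codes:
background 0, bark 1, intact 2, degraded 3, white rot 4. The finer
histological distinctions sometimes drawn on real wood (functional vs
nonfunctional intact tissue, reaction zones, dry tissue, clogged vessels) are
deliberately folded into these three analysis tissue classes; they are never
separate classifier targets.

## Phantom generator

Because no imaging dataset of diseased vines is deposited, all experiments run
on seeded synthetic specimens designed to carry exactly the statistical
structure the downstream methods rely on — and nothing subtler.

**Geometry.** A trunk is a cylinder of configurable radius (default 16 mm)
and length (78 mm) whose cross-section center is displaced sinusoidally in x
and y (amplitude 3 mm, wavelength equal to the trunk length, random phase) to
emulate the tortuous habit of a liana. A bark shell (2 mm) wraps the wood.
Above the trunk head, one or two narrower cylinders (6 mm radius) stand in
for branches so that the "+5 cm" region above the head exists.

**Lesion.** Wood voxels are ranked by an axially elongated Euclidean distance
(z compressed by a factor 2) from a lesion center placed on the trunk axis
10 mm below the head — decayed compartments on real trunks are continuous,
concentrated at the trunk top, and elongated along the axis. The closest
voxels form the lesion superset sized to the requested degraded + white-rot
fractions of wood; the white-rot core is the smallest-distance subset of the
superset's 26-connectivity erosion. This guarantees, by construction, that
every white-rot voxel touches only white-rot or degraded voxels, and raises an
explicit error when the requested core cannot fit. Realized fractions are
within ±2% of wood volume by counting.

**Signal model.** Intensities are relative: the intact class mean is 100 in
every modality, and degraded / white-rot means follow by chaining the measured
relative declines (intact→degraded: −19.3% X-ray, −57.3/−86.3/−71.3%
T1w/T2w/PDw; degraded→white rot: −56.0% X-ray, −36.8/−76.8/−64.2%). No
absolute units are meaningful, only inter-class changes. Bark (not reported
for real vines) is set to 60% of intact in the MRI channels and 90% in X-ray
— values chosen only to make bark separable, and configurable. Background is
0. Per-class intensity spread defaults to 10 units (10% of the intact mean);
`PhantomSpec.noise_sd` rescales the whole spread table, so `noise_sd=0` gives
exact class means. Noise is Gaussian, spatially smoothed (Gaussian kernel,
correlation length 1.2 voxels, variance renormalized analytically from the
kernel's sum of squares) to mimic the spatial texture of reconstructed
images.

**Cohorts and histories.** Cohorts are assigned round-robin to four
foliar-symptom history categories: *asymptomatic-always* (no symptoms in any
year), *asymptomatic-resilient* (symptoms in earlier years only),
*symptomatic-neo* (first symptoms in the observation year, 2019 by default),
*symptomatic-apoplectic* (sudden dieback in the observation year). Lesion
burden is a linear function of the cumulative number of symptomatic years
(degraded fraction 0.05 + 0.045·c, white rot 0.015 + 0.021·c, ±15% per-vine
jitter), with category-wise year counts always=0, resilient=2–3, neo=1,
apoplectic=4–6. Always-asymptomatic vines therefore carry the smallest
lesions and apoplectic vines the largest; the neo category sits below
resilient because burden tracks cumulative years, not the latest flag — this
is what lets the single-year symptom flag correlate poorly with inner
contents while the lifetime sum correlates strongly, the contrast the
history-correlation analysis measures.

**Reproducibility.** All randomness uses numpy's PCG64 generator. A cohort
derives per-specimen streams from the root seed by fixed offsets
(`default_rng([seed, i])`), so specimens are independent but bit-reproducible;
identical spec + seed gives bit-identical volumes.

**What the phantoms do not contain:** MRI physics (relaxation, bias fields),
CT beam hardening or ring artifacts, registration error between modalities,
within-class intensity gradients, anatomical microstructure (rays, vessels,
growth rings), or partial-volume mixing at native resolution. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
well-calibrated on data matching its own assumptions — not that the
classifier would reach the same scores on real trunks.

## Feature bank

Filters act per modality, isotropically in voxel units (the registered grid
is near-isotropic; anisotropy correction is deliberately omitted), on full 3D
neighborhoods, with edge replication at borders for bit-reproducibility.
Local mean/variance/min/max/median use a cubic neighborhood of half-width
`scale`; the edge detector is the Gaussian gradient magnitude at
sigma = scale; the difference of Gaussians is blur(scale) − blur(2·scale);
the raw intensity is always included as a channel (the trainable-segmentation
convention). Local variance is computed on a globally centered copy
(E[v²]−E[v]² after subtracting the volume mean) to avoid catastrophic
cancellation — this keeps it within 1e−9 of the brute-force definition. The
canonical scale set is powers of two 1–64; the scale may not exceed the grid
extent. Channel order is fixed (modality order, then raw, then
operator × ascending scale) so schemas are comparable across runs.

## Classifier

A random forest (default 200 trees, √(n_channels) features per split,
unlimited depth — trainable-segmentation-era defaults, all exposed) is fit on
annotated rows after a canonical sort (label, coordinates, specimen), making
the model invariant to input row order at fixed seed. Prediction uses hard
per-tree votes with ties broken toward the lower class code; the per-class
vote-fraction maps are therefore exactly consistent with the label maps, and
a single-tree forest yields {0,1} fractions. Models refuse feature stacks
whose channel schema differs from training, and record the training specimens
and per-class counts for leakage audits. No class re-weighting is applied;
the annotation sampler's per-class cap plays that role, mirroring capped
manual labeling.

## Validation protocol

All C(n,2) leave-two-specimens-out folds are enumerated in lexicographic
order of the held-out pair. Each fold trains only on the other n−2
specimens' annotations and scores only the pair's annotations; fold matrices
are summed into a global confusion matrix. Metrics come in closed form from
the matrix; a class absent from both marginals is reported as NaN
("undefined"), never as 0, while a present-but-missed class scores 0. Global
accuracy is reported both over all five classes and restricted to the three
tissue classes (rows of true tissue), since it is ambiguous which convention
a field report uses. Fold seeds derive affinely from the run seed and the
fold index, so modality-ablation and resolution variants are paired
fold-for-fold. The ablation repeats the protocol for all 15 non-empty
modality subsets, restricting channel columns of feature tables computed
once.

## Resolution degradation

Portable imaging is simulated by block aggregation: intensities are
block-averaged (not decimated — averaging matches how a lower-resolution
device integrates signal; strided decimation is not offered), labels take the
per-block majority with ties toward the lower class code, and partial edge
blocks use only their available voxels. The per-axis block factor is the
integer ratio of target to native spacing rounded to nearest (minimum 1): the
field convention quotes the ~0.68 mm native grid as "0.7 mm", and rounding
keeps that entry an exact identity, so the native rung of the sweep
reproduces the plain cross-validation bit-for-bit. The actual output spacing
(factor × native) is recorded alongside the requested one. Annotations are
converted by mapping annotated voxels to their coarse blocks and labeling
each block with the most represented label of that voxel volume, read from
the majority-downsampled ground-truth volume when available (majority over
the annotated voxels alone otherwise, which is noisier because annotations
are class-balanced rather than volume-proportional).

## Geodesic positioning

Tissue location along the trunk uses the shortest in-mask path from a
reference point at the trunk-axis center, by convention 200 mm below the
trunk head (phantoms scale this to min(200 mm, 0.8 × trunk length) so small
test geometries keep a meaningful head position). Paths step over
26-connected neighbors (6 by flag; the choice is a convention — 26 was
preferred as it better approximates Euclidean path length in tortuous masks)
with physical edge lengths from the voxel spacing, computed with a
minimum-cost-path solver and checked against an independent sparse-graph
Dijkstra to 1e−9. Signed position is (distance − reference depth)/10 in cm:
~0 at the trunk head, negative in the trunk, positive in branches. How an
analysis should sign root-ward voxels equidistant with trunk-top voxels is
genuinely ambiguous; phantoms place the reference so all wood of interest
lies on the upward path. The "upper 25 cm of the trunk" region is signed
position ∈ [−25, 0] cm; the head region used for staging is [−2, +2) cm.

## Staging and history comparison

Stage boundaries follow the published bands: white rot < 8% is *low*, 8–15%
*moderate*, > 15% *critical*, and intact ≤ 30% forces *critical* regardless
of white rot (critical describes vines with very limited intact tissue, so it
dominates). Both boundary values sit on the milder side (strict
inequalities), and all thresholds are configurable — an alternative 10/20%
white-rot banding discussed in the literature can be set via
`StagingThresholds`. Staging is piecewise-constant and monotone: more white
rot never improves the stage, more intact tissue never worsens it.

History categories are completed by a fifth class, *symptomatic-recurrent*
(symptoms in the observation year after earlier symptom years), so that every
flag pattern maps to exactly one category. Correlations between tissue
fractions and history covariates (observation-year flag, cumulative
symptomatic years, first-symptom year with never-symptomatic vines excluded)
are signed Pearson r — field reports sometimes label such signed values
"R²"; the report tags the method explicitly.

## Reference experiment sizes

The bundled protocols (`trunkphenix.protocols`) fix the desk-scale study
conditions: twelve phantoms on 64 × 64 × 160 grids at native spacing with
noise sd 10; thirteen annotated sections per specimen, at most 300 voxels per
class; features from all four modalities with the full operator list at
scales {1, 2}; 64-tree forests; and a resolution ladder {0.68, 2, 5, 10} mm.
Larger scale sets and forests are supported but add nothing measurable on
phantoms whose class contrast is piecewise-constant, while multiplying cost.
The signal-decline measurement pools 24 independent large phantoms
(128 × 128 × 192, ≥ 10⁵ voxels per tissue class each, ~44 M tissue voxels
pooled — the scale of a fully classified multi-vine dataset): the
degraded→white-rot declines divide by the small degraded mean (13.7 for T2w),
so a single phantom's correlated-noise sampling error (~1 percentage point)
is commensurate with the reporting precision, and pooling brings the standard
error near 0.2 points.

## Known limitations

- Phantom realism is intentionally minimal (see above); accuracy figures on
  phantoms are upper bounds relative to real trunks, where class contrast is
  weaker and annotation itself is uncertain.
- The geodesic sign convention cannot distinguish root-ward from head-ward
  voxels at equal path length; analyses restricted to the upper trunk are
  unaffected.
- Tissue-only metrics ignore background/bark spill-in when restricted to the
  tissue submatrix trace; the full five-class matrix is always reported for
  audit.
- The staging thresholds are variety-agnostic constants; real deployments
  would need variety-specific calibration.
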
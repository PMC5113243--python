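# Methods

Modelling and numerical choices behind `aaastress`, in pipeline order.
Conventions used throughout: volumes are arrays indexed `[z, y, x]` with
spacing and origin given as `(z, y, x)` in mm; in-plane points are `(x, y)`
mm; anterior is +y; octant angles are measured clockwise from anterior when
viewed from the feet, `angle = mod(atan2(dx, dy), 360°)`, with octant *k*
covering `(45(k−1), 45k]` degrees.

## Phantom

Each patient is built from an analytic per-slice geometry: an elliptical
outer wall whose baseline radius follows a Gaussian axial bulge (the
aneurysm sac), a constant-thickness wall obtained as the inward normal
offset of the outer ellipse, and a lumen formed by carving a raised-cosine
ILT crescent out of the wall cavity. Calcium is planted as small discs
inside the wall band. A rectangular vertebra with a smooth low-frequency
intensity pattern sits posterior to the aorta and serves as the registration
landmark. CT intensities are constant per tissue class (calcium = 1.5 ×
lumen); labels are written alongside as the segmentation reference.

Ground-truth octant composition (ILT and calcium area ratios, octant area)
is integrated on a 720-point angular grid. A provisional per-octant stress
uses the Laplace law, `σ ∝ MAP · r_lumen / (r_outer − r_lumen)`, averaged
over each octant and normalized per patient to a 0–1 scale over the included
(aneurysmal, anteroposterior diameter > 3 cm) octants. SUV_max per octant is
drawn from the generative model

```
suv = β₀ + β_s·stress + β_ilt·ilt + β_cal·cal + β_d·diameter + β_int·stress·ilt
      + b_patient + b_slice + b_octant + ε,     clipped at 0.05
```

with independent Gaussian random intercepts (`b_slice` nested in patient,
eight `b_octant` values drawn per patient) and planted SDs 0.158 (patient),
0.0186 (slice), 0.110 (octant), 0.30 (residual). Two stock parameter sets
exist: a univariate model (stress slope 0.552 only) and a multivariate one
(ILT −1.21 per unit ratio, i.e. −0.121 per 10%; stress:ILT interaction 1.0).

The aligned PET is painted as per-octant plateaus over the wall + ILT +
calcium band (ILT voxels scaled by a configurable attenuation, default 1.0),
then displaced by a planted rigid transform about the aorta centre and
optionally blurred by a Gaussian point-spread function. In
`integer_voxel` mode the planted offsets are whole voxels with zero
rotation and nearest-neighbour resampling, which makes the displacement
exactly invertible; combined with the plateau painting, a guard band at
octant boundaries (voxels within 1 mm arc of a 45° boundary take the
minimum of the two adjacent octants' values) and an axial margin that keeps
the aneurysmal extent away from the volume ends, the pipeline's sampled
octant SUV_max equals the planted value to machine precision. This is the
basis of the end-to-end exactness test.

A rendering-free path (`simulate_cohort`) integrates the same geometry
analytically and draws SUV from the same model, producing cohort octant
tables ~100× faster for statistical work.

## Segmentation

The lumen is grown from a seed voxel by connected thresholding on CT
(tolerance ±20% of the seed intensity). Per-slice lumen and outer-wall
contours come from sub-voxel marching squares on the masks; the outer
contour stands in for the manual outer-wall tracing of a clinical workflow.
ILT is derived, not segmented: the wall inner boundary is the outer contour
shrunk inward by the nominal 1.5 mm wall thickness (inward normal offset via
polygon buffering), and ILT is the region between that inner boundary and
the lumen. Calcium is thresholded at a configurable percentage (default
110%) of the mean lumen intensity within the wall band. Contours are
axially smoothed with a 3-slice moving average of their radial functions.

## Wall mechanics

Per slice, the wall annulus between the (ILT-ignoring) inner and outer
contours is meshed with quadrilaterals (radial × circumferential structured
grid, CCW node ordering) and solved as small-strain plane strain with
bilinear Q4 elements and B-bar selective reduced integration to avoid
volumetric locking at ν = 0.49. Materials: wall E = 2 MPa, ILT 0.2 MPa,
calcium 20 MPa, all ν = 0.49. Mean arterial pressure is applied as a
follower-free normal traction on the lumen boundary; rigid-body modes are
removed by pinning two nodes. Von Mises stress is evaluated at element
centroids; the top 5% of wall elements per slice are discarded as
numerical-artifact outliers before octant statistics. Against the analytic
Lamé thick-cylinder solution the max centroid error is 0.60%/0.19%/0.05%
at 4×64 / 8×128 / 16×256 elements (observed convergence order ≈ 1.8).

An optional "start shape" correction estimates the unpressurized geometry
by uniformly scaling contours so that the pressurized FE solution matches
the imaged diameter.

## Registration

PET is registered to CT by maximizing agreement of standardized intensities
(minimizing the SSD of z-scored values) over the vertebra mask, with 4
degrees of freedom (3 translations + axial rotation about the volume
centre). The mask is binary-eroded by 2 voxels first: the phantom PET has
already been resampled once when the misalignment was planted, so voxels
within ~2 voxels of the vertebra boundary carry interpolation-contaminated
values that otherwise dominate the metric. Optimization is a coarse grid
search followed by Powell restarts. Because the planted transform is
defined about the aorta centre and the recovered one about the volume
centre, recovery is asserted by comparing the transforms as point maps, not
by comparing raw parameters; planted offsets up to ±10 mm / ±5° are
recovered to within 0.3 mm / 0.3°.

## Octant sampling

The aneurysmal extent is every slice with outer anteroposterior diameter
> 3.0 cm, plus a proximal neck margin of 6.5 mm. Each included slice is
divided into eight 45° sectors about the lumen centroid. SUV_max per octant
is the maximum registered-PET value over wall-band voxels (between lumen
and outer contour) in the sector; composition ratios are sector areas of
ILT and calcium over the sector wall-cavity area; per-octant stress is the
mean retained von Mises wall stress of the sector, normalized per patient.
A per-voxel brute-force implementation of the same definitions serves as
the test oracle. A partial-volume sensitivity re-extracts SUV_max with the
wall band widened inward by one pixel.

## Statistics

The linear mixed model has fixed effects for normalized stress, ILT ratio,
calcium ratio, outer and lumen diameter and the stress×ILT interaction, and
random intercepts for patient, slice-within-patient and octant number. It
is fit by a custom profiled REML/ML routine: conditional on the three
variance ratios, fixed effects and the residual variance have closed forms
(per-patient Woodbury blocks), leaving a 3-parameter Nelder-Mead search
over log variance ratios. REML is used for reported coefficients and SDs,
ML for AIC-based comparisons (backward elimination that never drops a main
effect while its interaction remains, and the null-vs-full ΔAIC for the
stress terms). The fit matches `lme4::lmer` to six decimals on reference
problems, and `statsmodels` MixedLM serves as an independent oracle in the
test suite. Rank-deficient designs (e.g. an all-zero calcium column in a
tiny run) raise an informative error; the pipeline's analysis stage drops
constant columns before fitting and records what it dropped.

Discrimination is summarized by empirical ROC curves of normalized stress
against the high-uptake label (SUV_max above a configurable cutpoint),
overall and within ILT strata, with trapezoid AUC (verified equal to
all-pairs concordance) and Youden-J thresholds; group contrasts use
Mann-Whitney or Welch tests chosen by a normality screen.

## Pipeline and reproducibility

Stages run from a single YAML `RunConfig`; every threshold named above
(calcium 110%, discard 5%, cutoff 3 cm, neck 6.5 mm, SUV cutpoint 2.0,
stress threshold 0.45, ILT strata 0.33/0.67) is a config field, never a
hard-coded constant. One global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence((seed, stage_index))`, so stages are
independently reproducible and identical configs yield byte-identical
outputs. `manifest.json` records the config SHA-256 and the SHA-256 of
every artifact; a failing stage still writes the manifest with the error,
preserving partial outputs.
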
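# Methods

This note documents the models, defaults and numerical choices behind
paintbox, and what the synthetic studies do and do not show.

## Grids and resampling

A volume is a scalar field on an axis-aligned lattice; voxel indices are
0-based in (x, y, z) order and the world position of the center of voxel
(i, j, k) is `origin + (i, j, k) · spacing` (mm).  Resampling samples the
source interpolant at the world coordinates of the target voxel centers:
nearest, trilinear, or cubic B-spline with mirror boundary for the
prefilter.  Points outside the source voxel-center hull take the fill
value 0.  Indices that are integer up to 1e-9 are snapped so all three
interpolants are exact on the identity regrid.  Masks must be resampled
with nearest neighbor so they stay binary; segmentation always operates on
resampled SUV, never on interpolated masks.

The planning chain uses the interpolation combination selected by the
two-stage co-registration study (`coregistration_chain_study`, which
reproduces the measured-volume / percent-deviation table layout on a
known-volume tube phantom): cubic spline for the PET-to-CT-grid fusion,
then nearest neighbor onto the dose-calculation grid.  Skipping the
CT-grid stage and jumping PET-grid → dose-grid with nearest neighbor
noticeably degrades plan quality for the coarse-voxel protocol — the
prescription inherits 3.2 × 3.2 × 5 mm blocks that no deliverable dose can
follow — which is the practical reason the chain matters.

## Phantoms

Lesions are analytic solids (sphere, z-axis cylinder, ellipsoid) with
uniform activity in SUV units; heterogeneous uptake is modeled by nesting
(a child lesion overrides its host inside a smaller shape).  The default
planning phantom is head-and-neck-like: a soft-tissue cylinder (relative
density 1, radius 52 mm), a posterior 5 mm-radius cord-like OAR, and three
separate lesions of 5.6, 3.1 and 2.3 ml with base activities 6/5.5/7 and
hot cores at 10/9/11 — three distinct targets with distinct internal
gradients, activity levels chosen so all three survive segmentation at 40%
of the global maximum after blurring.  A second stock phantom carries the
known-volume references for the resampling study: a 0.3 ml sphere, plus a
0.3 ml sphere nested in a 2.0 ml cylinder at a 4:1 activity ratio
(heterogeneous-lesion surrogate).  Activities are specified directly in
SUV units; no scanner calibration is modeled.

## Reconstruction emulation

A protocol is emulated at the effect level, in the order of a real
reconstruction chain: Gaussian blur of the residual point-spread FWHM in
world units on the fine truth grid, linear resampling to the protocol
grid, voxel-wise multiplicative Gaussian noise `1 + cv·N(0,1)` (clipped at
0, CV default 0.05; the paper-silent noise level was fixed once at a
typical whole-body-PET magnitude), then the post-processing Gaussian
filter applied to the noisy image — so surviving noise is correlated at
the filter scale, as in real images.  Defaults:

| protocol | voxels (mm) | residual PSF | post filter |
|----------|-------------|--------------|-------------|
| EARL-style harmonized | 3.2 × 3.2 × 5 | 5 mm | 6 mm |
| scanner-native (PSF recon) | 1.6 × 1.6 × 1.5 | 2 mm | 3 mm |

The residual-PSF values encode that resolution-modeling reconstruction
recovers most intrinsic blur while plain OSEM does not.  The emulation
reproduces the downstream-relevant phenomena — partial-volume dilution of
small lesions, threshold volumes that differ between protocols by more
than a scale factor — but not sinogram statistics, attenuation/scatter
artifacts or iteration-dependent convergence, so conclusions about
absolute SUV accuracy do not transfer to real scanners.

## Prescriptions

Segmentation is a fixed-fraction threshold of the maximum SUV (default
40%) with small 26-connected components removable — a declared
simplification of cluster-based segmentation that preserves
multifocality.  The DPBN map is the min–max linear SUV→dose mapping with
endpoints 70 and 82 Gy; the DPBC map thresholds nested BTVs and, by
default, gives each subvolume the DPBN dose of its threshold SUV so the
two discretizations are mutually consistent.  Similarity factors default
to (0.97, 1.03): the robust band equals the tightest clinically reported
Q tolerance, and the LP enforces floors as `D·Δ_min` and ceilings as
`D·Δ_max`.  When maps are stacked, every map keeps its own constraint pair
per voxel (intersection semantics — stacking can only tighten), and OAR
voxels inside the target union are released from their cap (target
priority).  Conflicting stacks are legal; the slacks absorb the conflict
and the optimizer returns the best compromise.

## Apertures and dose

Apertures are generated from the image, not from intensity maps: each
prescription band (per-voxel dose quantized into 4 nested levels, banded
per connected component so each lesion is quantized over its own dose
range) is projected along each beam by parallel-ray line integrals, and
each 2-D connected component of the projection becomes one aperture whose
leaf rows (4 mm leaf width) open to the convex hull of the component in
that row.  The outer shapes (conformal and band 0) are grown by a block
margin of 6.5 mm ≈ 1.6σ before the hull is taken, placing the ~95%
fluence level — not the 50% falloff — at the projected target edge; inner
boost bands get no margin because their edges are free gradients inside
the target.  Seven equispaced coplanar beams are the default.  On the
default phantom this yields ~70 apertures for a single-map plan and ~140
for a two-map robust plan (shapes are generated from every stacked map and
de-duplicated geometrically).

Dose per unit weight comes from an analytic pencil-beam kernel:
exponential attenuation `exp(−μ·radiological depth)` (μ = 0.005/mm,
density-weighted path length computed on a beam-aligned auxiliary grid)
times a Gaussian lateral penumbra (σ = 4 mm) integrated in closed form
(erf) over each open leaf-row rectangle.  Columns are truncated at 1e-6 of
their maximum and stored sparse.  The kernel is linear and deterministic,
which makes the influence matrix exact for the LP and testable against
dense superposition; it reproduces clinically shaped depth doses and
penumbras but none of the scatter, spectral or MLC fine structure a Monte
Carlo engine would give.

## Optimization

The plan LP (weights + per-constraint slacks, objective = penalty-weighted
slack sum, defaults P_T,max = P_T,min = 1, P_OAR,max = 0.5) is solved with
HiGHS at 1e-7 feasibility/optimality tolerances.  With free slacks the
problem is always feasible and bounded.  Because the ±3% band makes the
optimum degenerate, a lexicographic second pass selects among
objective-optimal plans the one minimizing the worst per-map mean relative
deviation from the prescription (plus a 1e-3-weighted total-deviation term
for uniqueness): with one map this centers the dose on the prescription,
with several it picks the evenly balanced compromise.  The reported
objective is recomputed analytically from the returned weights
(`recover_slacks`), which also serves as the independent oracle: for any
weights the optimal slacks are `x = max(0, dose − ceiling)`,
`y = max(0, floor − dose)`.  Weights are unbounded above by default.

## Evaluation and adaptation

Q, QVH, QF, strict tolerance fractions, DVH and the conformity index
follow the standard definitions; CI is interpreted as target coverage
(fraction of structure voxels receiving ≥ 95% of their own per-voxel
prescription), the reading under which CI ≤ 100% always holds.  QVH bins
default to 0.01 in Q, DVH bins to 0.1 Gy; tolerance comparisons are
strict inequalities.

Adaptive replanning keeps the prior aperture pool, adds the shapes the
follow-up prescription generates (dropping near-duplicates, edges within
half a fluence pixel), computes influence columns only for the new shapes
and re-solves the LP — so an unchanged prescription cannot worsen the
objective.  Phase doses are planned as full-course doses and accumulated
voxel-wise with fraction weights (default 17/30 and 13/30) on the shared
rigid grid; no deformable registration is modeled.  The total course is
evaluated against the fraction-weighted prescription over the voxels
prescribed in every phase: where a later phase stopped prescribing
(resolved disease) there is no full-course prescription to compare with,
and those voxels are excluded from the total-treatment Q statistics.  For
hybrid (multi-map) plans, Q is reported against each map separately rather
than against any blended reference.

## Problem sizes and limitations

The default studies run on a 2 mm dose grid (60 × 60 × 45 voxels over a
12 cm phantom — the fine-grid end of clinical practice, chosen because
coarse dose grids visibly alias the voxel-wise prescriptions), a 1 mm
activity-truth grid, and a CT-like 1.52 × 1.52 × 1.5 mm fusion grid; a
full single-map plan takes ~10 s and a robust two-map plan ~30 s on one
CPU.  Known limitations: parallel-ray geometry (no divergence), no MLC
leaf-end/tongue-and-groove or delivery-time modeling, threshold
segmentation instead of clustering, and an LP without dose-volume or
biological-outcome constraints.  Passing quality thresholds on these
phantoms demonstrates the method's internal consistency at realistic
noise and resolution, not clinical performance on patient anatomy.
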
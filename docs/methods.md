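# Methods

`scalpmap` implements a four-part analysis of how the macroanatomy of the
infant lateral cortex co-develops with the head, using the scalp-based
10-20/10-10 positioning system as the frame of reference.  Everything is
exercised on a synthetic cohort with known ground truth, so each statistical
claim made by a green test is a claim about recovery of injected effects,
not about real infants.

## Coordinate conventions

All coordinates are millimetres in the AC-PC frame: origin at the midpoint
of the anterior and posterior commissures, +x left to right, +y posterior to
anterior along the AC-PC line, +z inferior to superior in the midsagittal
plane.  `acpc_align` builds this frame by Gram-Schmidt from AC, PC and one
midsagittal point and returns a proper rigid transform (rotations only,
det +1); it raises on collinear inputs.

## Surface curves

Scalp curves are plane-section polylines, not true geodesics: the curve
between anchors `a` and `b` is the intersection of the mesh with the plane
through `a`, `b` and a third anchor, and of the two sub-arcs between the
anchors the one passing nearest the third point is kept.  This matches the
construction lineage of virtual 10-20 positioning methods and is exact on
spheres.  Intersection points are computed per crossing edge and chained
through shared mesh edges, so no tolerance-based stitching is involved;
anchor snap distances are bounded by `max(0.5 mm, 0.75 x median edge)`.
Ray-mesh queries use a vectorized Möller-Trumbore test and return the
outermost (largest-parameter) crossing.

## Virtual 10-20/10-10 positioning

Cz is the fixed point of the alternating construction: midpoint of the
Nz->Cz->Iz arc, then midpoint of the AL->Cz->AR arc, iterated until Cz moves
less than 0.1 mm (max 50 iterations; deterministic start at the topmost mesh
vertex).  The montage is then built from

* the midline curve Nz->Cz->Iz, subdivided at 10% steps (Fpz ... Oz);
* the central coronal curve AL->Cz->AR, subdivided at 10% steps (T3 ... T4);
* the circumferential ring, built as two half-ring plane sections
  (Fpz->T3->Oz and Fpz->T4->Oz) with positions at 20/40/60/80% of each
  quarter (5% of the ring per step);
* transverse rows joining a left ring point, a midline point and a right
  ring point, subdivided per half so the midline point lies exactly on the
  curve (e.g. F3 at the midpoint of F7->Fz).

Label/fraction tables ship as editable JSON data
(`data/montage_definitions.json`).  Classic names T3/T4/T5/T6 are used.
Under the per-half convention the 25-point 10-20 set (19 electrodes + Fpz +
Oz + 4 fiducials) is an exact subset of the 10-10 montage, which contains 65
labeled positions here.  The per-half reading of "subdivide into 4 (or 8)
equal arcs" was chosen over whole-curve fractions because it keeps already
placed through-points exactly on their curves; on symmetric heads the two
conventions coincide.

## Procrustes shape analysis

Partial generalized Procrustes: each configuration is centered, scaled to
unit centroid size (the square root of summed squared distances from the
centroid — the analysis explicitly scales by centroid size, with no
additional full-Procrustes cos-rho factor), and rotated to the running
consensus by the optimal proper rotation (SVD with determinant correction;
reflections are never applied, so a mirrored configuration keeps a large
residual).  The consensus is the renormalized mean, iterated to 1e-8 (max
100 iterations).  After convergence the consensus is rotated to a canonical
orientation (principal axes onto x/y/z, signs fixed through the
largest-magnitude elements of the *left* singular vectors, which are
basis-independent; the third axis is the cross product of the first two).
This makes the aligned coordinates deterministic and invariant to rigid
pre-transforms and input order.

PCA operates on mean-centered flattened Procrustes coordinates via SVD;
scores reproduce the data to 1e-9 and each component's largest-magnitude
loading element is positive.  PC signs are otherwise arbitrary, so the sign
of a score-age correlation is convention-dependent; magnitudes are not.
Tangent-space projection is omitted (shape variation here is small compared
to the curvature of shape space); this is a deliberate simplification.

Two standard configurations: "cortex" = landmark ids 7-15 and 20 on each
hemisphere (k = 20; ids 1-6 are extreme points rather than macroanatomical
structures, and 16-19 are dependent on landmark 11's slice), and "head" =
the 25-point 10-20 montage (k = 25).

## Distance-ratio statistics

For a triple (a, b, c) the ratio d(a,b)/d(b,c) is computed either directly
or after projection to the sagittal (x := 0) or coronal (y := 0) plane; the
mode is fixed per table row (`data/table1_specs.tsv`).  A declining
frontal-to-occipital share means the middle landmark shifts anteriorly; a
declining vertex-to-base share means a dorsal shift; this direction
metadata is carried in the table.  Junction landmarks (8, 9, 10, 11, 12,
20) are first adjusted to the cortical surface by a lateral (+/-x) ray from
the midline to the outermost brain-surface crossing, which removes
depth-direction variability while preserving y and z; a missed ray falls
back to the nearest surface vertex with a logged warning.  Landmarks 16-19
are slice-dependent: their y coordinate is re-imposed from landmark 11
before lateral re-projection whenever a brain mesh is available.

Correlations with age use Pearson r with the exact two-tailed p from
t = r sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.  p values are
displayed to 3 decimals with round-half-even; raw values are retained.  A
ratio series whose variance falls below a 1e-10 relative threshold is
reported as r = 0, p = 1 (the degenerate constant case produced by a
shape-preserving cohort); `pearson_with_p` itself raises on zero variance.
No multiple-testing correction is applied.

## Cortical-to-scalp transfer

A cortical point CP is written as CP - M = a1(L1-M) + a2(L2-M) + a3(L3-M),
where M is the AL-AR midpoint and L1-L3 are the three neighboring 10-10
positions; the 3x3 system is solved exactly (residual <= 1e-9 mm).
Neighbors are the nearest montage positions by Euclidean distance subject
to {Li - M} being linearly independent (condition number < 1e6); on
degeneracy the farthest member of the triple is replaced by the
next-nearest candidate, with ties broken by label order.  Distance ranking
uses the landmark's own scalp projection (ray M->CP extended to the subject
scalp) so deep landmarks select lateral rather than vertex neighbors; the
four fiducials are reference points, not candidates.  The coefficients are
re-applied to the template's M and 10-10 positions, and the reconstructed
point is back-projected to the template scalp along the ray M->CP_t --
i.e., all three coefficients are enlarged by one common factor, the only
interpretation that preserves direction (per-coefficient scaling would be
underdetermined).  Per-landmark scatter is summarized by distances from the
cloud centroid with linear-interpolation quartiles and Tukey whiskers at
1.5 IQR, and compared against the montage's nearest-neighbor pitch.

## The synthetic cohort

The generator emulates the stated world: n = 16 subjects, ages spread over
3-22 months with jitter.

* **Geometry.**  The brain is a superellipsoid |x/a|^p + |y/b|^p + |z/c|^p = 1
  (squareness p = 2.5) with semi-axes (52, 57, 44) mm at age 0 growing at
  (0.45, 1.10, 0.70) mm/month — length fastest, then height, then width.
  Absolute sizes are configurable assumptions (12-month brain length
  ~140 mm), not measured facts.  The scalp is the brain dilated by 8 mm;
  fiducials sit at its parametric extremes, noise-free.  Meshes are
  radially mapped icospheres (watertight by construction).
* **Landmarks.**  40 landmarks (20 per hemisphere) at fixed parametric
  directions; 16-19 are constructed on the coronal slice of landmark 11.
* **Drifts.**  Anterior drifts on 8, 9, 10 (0.60 mm/month) and 12
  (0.50 mm/month), a dorsal drift on 14 (0.60 mm/month), and one lateralized
  ventral drift on 18R (0.25 mm/month); drifted points are re-projected to
  the surface.  Rates were calibrated by simulation so the ratio/age
  correlations land at |r| ~ 0.66-0.70 for n = 16 under default noise (the
  generator's stated effect-size band), then frozen.
* **Noise.**  Iid isotropic Gaussian noise, sigma = 2.16 mm, on every
  landmark.  Two independent localizations of the same point then differ by
  2.2568 sigma ~ 4.87 mm on average (the mean of a 3-D Gaussian norm with
  per-axis sd sigma*sqrt(2)), matching the reported inter-rater distance.
* **Null world.**  `GrowthModel.null()` is a spherical brain growing by
  pure uniform scaling with no drift.  Equal *additive* slopes on unequal
  semi-axes would still change shape, so the null uses equal semi-axes and
  equal slopes; every distance ratio is then exactly age-invariant and the
  ratio/age test's type-I error can be measured cleanly.

What the generator does **not** model: gyrification and real sulcal
geometry, MRI contrast and segmentation error, fiducial localization noise,
hemispheric petalia, and non-ellipsoidal head shape.  Consequences worth
knowing: with noise-free scalp and fiducials the head-shape space is
essentially a one-parameter growth trajectory, so head PC1 absorbs ~100% of
variance and correlates with age near |r| = 1 (real data, with scalp
extraction and fiducial noise, spreads this over several components); and
cortical PC1-age correlations are stronger than in real infants because the
only variation besides the injected drifts is isotropic rater noise.  Green
tests therefore establish that the pipeline recovers known effects at
realistic noise, not that real infant anatomy behaves this way.

## Numerical choices

* mesh point-on-surface tolerance 0.5 mm (configurable); arc endpoint snap
  bounded by 0.75 x median edge length;
* Cz tolerance 0.1 mm, max 50 iterations; GPA tolerance 1e-8, max 100;
* neighbor-triple condition-number bound 1e6; decomposition residual bound
  1e-9 mm;
* quartiles use numpy's linear interpolation; whiskers are Tukey 1.5 IQR;
* all randomness flows from a single root seed through
  `numpy.random.default_rng([seed, subject_seed])` spawns, making every
  stage bit-reproducible;
* degenerate inputs raise typed errors (collinear frame, zero-length arc,
  ray miss, rank-deficient configuration, zero-variance correlation,
  zero-denominator ratio) rather than returning sentinel values.

## Known limitations

* Plane-section curves differ from geodesics on strongly aspheric heads;
  the positioning literature itself uses the plane-section construction.
* The 10-10 label set implemented is the 65-position superset needed by the
  analyses; the 10-5 system is out of scope.
* With landmark noise of a few millimetres, surface adjustment can place a
  point slightly off its true slice; the slice constraint for 16-19 is
  re-imposed only when a brain mesh is supplied.
* The transfer's neighbor choice is nearest-by-Euclidean (after scalp
  projection); nearest-by-geodesic is a documented alternative not enabled
  by default.
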
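# Methods

`sasmorph` measures the width of the subacromial space (SAS) — the gap
between the humeral head and the acromion — from binary bone segmentation
masks, and quantifies how well two raters or two imaging modalities agree on
repeated width measurements. This note documents the models, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## Geometric pipeline

**Input.** Two co-registered 3D binary masks (humerus, acromion) with a
NIfTI affine giving voxel spacing and origin in RAS millimetres. All
downstream geometry lives in world millimetres; voxel indices are 0-based.

**Smoothing.** Each mask is blurred with a Gaussian of variance
`variance_mm2` (default 1.56 mm², i.e. σ ≈ 1.249 mm). The kernel is
isotropic in *physical* space: the per-axis sigma in voxel units is
σ/spacing, so anisotropic grids (e.g. 0.8 × 0.8 × 1 mm) are handled
correctly. The result is an occupancy field in [0, 1]. Whether the source
material intended the smoothing to be isotropic in mm or in voxels is not
determinable from its description; mm-isotropic is the default here because
it makes the extracted geometry independent of grid anisotropy, and the
variance is config-exposed.

**Surface extraction.** Marching cubes at `iso_level` (default 0.5, the
midpoint of a blurred binary edge; the level is not dictated by anything
upstream, so it is configurable). The largest connected component is kept —
each mask contains one bone, so smaller fragments are speckle. Winding is
made consistent and, for watertight meshes, oriented so signed volume is
positive (outward normals).

**Resampling.** Meshes are resampled to `n_resample` vertices (default
10,000) by Voronoi-style clustering: vertices of the (if necessary,
subdivided) source mesh are partitioned into `n_resample` compact clusters
by seeded Lloyd iteration (random-vertex initialisation, KD-tree
nearest-centre assignment, 15 sweeps), each cluster contributes its centroid
as one output vertex, and source faces spanning three distinct clusters
become output faces. On a uniformly triangulated surface the clusters have
near-uniform area, which is the property the resampling exists to provide.
The source mesh is subdivided until it has at least 3× the target vertex
count, so no cluster is a single vertex; output counts land within ±2% of
the target.

Output vertex normals are the area-weighted average of the *source* mesh's
outward vertex normals over each cluster, not normals recomputed from the
decimated faces: face pairs that collapse onto the same cluster triple carry
arbitrary winding, and recomputed normals would flip at isolated vertices.

**Vertex normals.** Area-weighted: each face's cross product (magnitude =
2 × area) is accumulated onto its three vertices and normalised. Degenerate
(zero-area-neighbourhood) vertices are reported in the provenance log and
given a placeholder unit vector. On a regularly triangulated sphere these
normals are radial to well under 2°; on a marching-cubes mesh of a voxelized
sphere, faceting noise leaves a tail of up to ~6° at 0.8 mm spacing — a
property of the mesh, not the estimator, and one reason the distance map is
computed on the resampled surface.

**Distance map.** From every acromion vertex a ray is cast along the
outward vertex normal with a `max_ray_mm` budget (default 50 mm). Only the
humerus is intersection-tested, so the acromion never occludes itself;
first-hit semantics apply, and the recorded value is the Euclidean
origin-to-hit length. Misses are NaN. The intersection kernel is a
vectorised Möller–Trumbore over spatially sorted ray chunks with an
axis-aligned-bounding-box prefilter per chunk; it is exact (validated
against a brute-force all-triangles oracle to 1e-9 mm) and runs 10⁴ rays
against 10⁴ triangles in a few seconds on one core. Rays are cast outward
only by default — on anatomy the inferior acromion's outward normals face
the humerus; `bidirectional_rays` exists for meshes with unreliable
orientation.

**Summary measures.**

* `MRI_Hum10`: the mean of the m = max(1, round(0.10 · n_valid)) smallest
  finite distances. The 10% fraction is taken over vertices whose ray *hit*
  (vertices with no intersection have no distance to rank); the alternative
  convention — fraction of all resampled vertices — is available via the
  `hum10_fraction` config for sensitivity analysis. Ties at the cutoff are
  resolved in stable vertex-index order, which can only affect membership
  among equal values and therefore never the mean.
* `MRI_Lat`: the acromion vertex with the extreme coordinate along
  `lateral_axis` (default `+x` in RAS — the patient's right, appropriate
  for a right shoulder; use `-x` for a left) is selected, ties toward the
  smallest index; the measure is the minimum Euclidean point-to-triangle
  distance from that vertex to the humerus, *not* restricted to the normal
  direction, since it stands in for the lateral width visible to
  ultrasound. Whether the lateral point should be constrained to vertices
  with valid ray hits is an open convention; it is not constrained here.

## Synthetic phantom

A sphere (humeral head, default radius 20 mm, centred at the origin) plus a
rectangular plate (acromial shelf, default 30 × 30 × 8 mm) whose lower face
sits `gap_mm` above the sphere apex, optionally tilted about the
anteroposterior axis. The minimum solid-to-solid distance is closed-form
(point-to-oriented-box distance of the sphere centre minus the radius; for
zero tilt it equals `gap_mm` exactly), so the whole geometric pipeline can
be validated against ground truth. Voxelization marks a voxel foreground
iff its centre lies inside the solid — unbiased under refinement. The
default spacing is 0.8 × 0.8 × 1 mm, matching a typical coronal T1 gradient-
echo shoulder protocol.

What the phantom does *not* emulate: cortical/trabecular intensity,
segmentation error, soft tissue, or anatomical curvature of the acromion.
Pipeline accuracy numbers on the phantom therefore bound discretisation and
meshing error only, not rater or segmentation variability.

Measured behaviour (recomputed by the test suite, not asserted from
memory): at the default spacing the recovered `MRI_Hum10` sits within
~0.3 mm of the true 9.5 mm gap, with the absolute error monotonically
non-increasing over a 2.0×/1.5×/1.0× spacing refinement, and both summary
measures strictly increasing over a 5-value gap ladder. `MRI_Hum10` is
biased slightly *above* the true minimum by construction (it averages the
closest 10% of points, which lie on the sphere's shoulder as well as its
apex).

## Rater simulation

Repeated measurements follow the additive two-way random-effects model
under which ICC(2,1) is defined:

    y[s,r,t] = μ + subject[s] + bias[r] + rater_effect[r]
               + interaction[s,r] + ε[s,r,t]

with subject ~ N(0, σ_s²), per-table random rater effects ~ N(0, σ_r²),
subject × rater interaction ~ N(0, σ_sr²), noise ~ N(0, σ_e²), and fixed
per-rater offsets `bias`. Defaults mirror a healthy-adult two-rater cohort:
18 subjects, 2 raters, 3 repetitions, mean width 11.4 mm, between-subject
SD 2.0 mm, a 1.3 mm systematic offset for the less experienced rater, and
0.7 mm repetition noise. After averaging the m repetitions the implied
population ICC(2,1) is

    σ_s² / (σ_s² + var(bias) + σ_r² + σ_sr² + σ_e²/m)

and is returned with every simulated table, so calibration experiments have
an exact target. `RaterSimSpec.for_population_icc` inverts this for the
bias-free, single-repetition case.

## Agreement statistics

**ICC(2,1)** (single measure, absolute agreement, two-way random effects)
is computed from the ANOVA mean squares of the complete n × k table:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

The 95% CI uses the standard F-based construction with a Satterthwaite
degrees-of-freedom approximation. CIs are reported truncated to [0, 1] (the
conventional display) with the raw bounds retained. A constant matrix has
no defined ICC and raises rather than returning a value. Empirically the
estimator carries the known small-sample downward bias (~0.02 at n=18,
k=2, ICC 0.5); at 500 Monte-Carlo tables the standard error of a mean
estimate is ~0.009, so recovery checks at the 0.03 level include both bias
and sampling noise.

**Post-hoc power** for the two-tailed test of ICC = ρ₀ (default 0) uses the
Fisher z transformation: with Δ = atanh(ρ₁) − atanh(ρ₀) and standard error
SE,

    power = Φ(Δ/SE − z₁₋α/₂) + Φ(−Δ/SE − z₁₋α/₂).

The default SE is 1/√(n − 1). This choice is empirical: across the full
range of two-rater ICCs with published powers at n = 18 (0.21 through
0.74), 1/√(n − 1) reproduces every printed power exactly at two decimals,
while the classic pairs variant 1/√(n − 3/2) and the large-sample
1/√(n − 2) each miss several by 0.01. All three are selectable via
`se_method`, plus a general-k form √(k/(2(k−1)(n−2))). ρ₁ = ρ₀ returns α
(the test's size) as the degenerate limit.

**Bland–Altman**: bias = mean difference (orientation a − b, declared per
comparison; conventions here are novice − expert and US − MRI), SD with the
n−1 denominator, limits of agreement bias ± 1.96·SD (multiplier
configurable), per-pair means retained for plotting.

**Calibration regression**: OLS of the MRI-derived width on the ultrasound
width, reporting intercept, slope, R², residual RMSE with n − 2 degrees of
freedom, and the overall-F p-value with a significance flag at 0.05. No
multiple-testing correction is applied across a battery of comparisons;
reports should say so when several regressions are shown together.

**Classification bands**: < 0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90]
good, > 0.90 excellent. The band edges at 0.75 and 0.90 are formally
ambiguous in common usage; the assignment above is this package's
documented convention.

## Numerical choices and degenerate inputs

* Ray-cast tolerances: determinant cutoff 1e-12, barycentric slack 1e-9,
  minimum hit parameter 1e-9 mm (self-intersection guard). Chunk size 192
  rays; results are independent of chunking (regression-tested).
* Point-to-triangle distance: barycentric projection where the foot lies
  inside the face, otherwise minimum over the three clamped edge segments.
* `sas_hum10` count: floor(x + 0.5) rounding, so exactly half-integers
  round up regardless of parity.
* Empty masks, all-zero fields, iso-levels outside the field range,
  incomplete subject × source matrices, constant matrices, zero-variance
  predictors and sub-minimum sample sizes all raise typed errors naming the
  violated precondition rather than returning NaNs.
* Heatmap export: legacy-ASCII VTK PolyData with a `sas_mm` POINT_DATA
  array (NaN for misses, stated in the header comment), or PLY with a
  per-vertex `sas_mm` attribute.

## Problem sizes used in the test suite

Simulation-based checks use 500 tables per condition (estimator recovery)
and 1,000 tables (CI coverage); geometric checks run the full pipeline at
10,000-vertex resampling on the default phantom and a coarse 2×-spacing
variant for ladders. These sizes keep the complete suite under a minute
while leaving Monte-Carlo margins (documented above) well inside the
asserted tolerances.

## Known limitations

* The phantom's plate is a poor stand-in for acromial curvature; `MRI_Lat`
  on anatomy depends on the declared lateral axis and on segmentation of
  the acromial edge, neither of which the phantom stresses.
* The resampler guarantees near-uniform *cluster* areas, not isotropic
  triangle quality; meshes with long thin input triangles keep some
  anisotropy.
* The Fisher-z power formula is an approximation whose SE convention is
  empirical (see above); for k > 2 the general-k variance is provided but
  has not been validated against published values.
* ICC variants other than (2,1) — e.g. consistency or average-measure
  forms — are out of scope; `pingouin` covers them if needed.
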
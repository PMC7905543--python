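# Methods

## Displacement measure

A fragment's motion between two poses is a proper rigid transform; the
package summarizes it by two parameters chosen to be intuitive, unit-bearing
and statistically independent.

**Fragment center.** The center is the center of the minimal-volume
oriented bounding box (OBB) of the fragment's vertex set. An OBB center is
reproducible and automatic; unlike the centroid of the vertices it does not
depend on mesh tessellation density, and unlike anatomical landmarks it
requires no human input. "Uniquely defined" holds only up to symmetry: a
cube admits 24 equivalent minimal boxes. The implementation canonicalizes
(half-extents sorted descending, axis signs fixed lexicographically,
right-handed frame), and — decisively — every minimal box of equal volume
shares the same *center*, which is the only OBB output consumed downstream.

**OBB search.** Exact minimal-volume OBB computation is cubic in the hull
size; the package instead uses the classic approximation family: convex
hull, candidate orientations from hull-facet normals (one box face flush
with a facet) with the in-plane orientation solved exactly by rotating
calipers, plus a coarse global orientation scan (6° grid) as a second
candidate source, and a Nelder–Mead polish over rotation-vector
perturbations of both candidates. The polish repairs the face-flush
restriction's residual; the coarse scan guards against a non-global valley.
The test suite checks the result against a 2° rotation-grid brute-force
bound: the implementation must cover all points and must not exceed the
brute-force volume by more than 0.1% (it is typically 0.1–1% *below* it,
since the grid quantizes orientation).

**Relative motion.** The motion `M = p₂ ∘ p₁⁻¹` is recovered from the two
posed vertex sets by Horn's closed-form quaternion solution with unit
weights: rotation from the dominant eigenvector of the 4×4 symmetric matrix
of the centered cross-covariance, translation from the centroids. A
rigidity guard rejects vertex sets whose pairwise distances differ by more
than 1e-6 × the mesh's bounding-box diagonal (e.g. meshes of two different
fragments passed by mistake); collinear point sets are rejected as
rotationally ambiguous.

**TFS and TFA.** `TFS = ‖M(c₁) − c₁‖` (mm); `TFA` is the rotation angle of
M's quaternion in degrees, computed with `atan2` rather than `arccos` for
stability near 0° and 180°. The pose-1 center is *mapped* through M rather
than recomputing the OBB in pose 2: the two coincide exactly for rigid
motion, and mapping makes TFS invariant to OBB tie-breaking and orientation
jitter. A diagnostic mode recomputes the pose-2 box and warns if the
centers disagree beyond 1e-6 × diameter. For a screw motion of angle θ
about an axis at perpendicular distance d from the center with axial slide
s, the closed form is `TFS = √(s² + (2 d sin(θ/2))²)`, `TFA = θ`; the test
suite sweeps this over >100 parameter combinations at 1e-9.

## Study statistics

Deviations (rater final pose vs gold final pose, per fragment) are averaged
per rater and case; case-level means are aggregated per rater into a mean
(performance) and a sample standard deviation with n−1 denominator
(consistency). The gold-standard rater is excluded everywhere — its
deviation is identically zero.

* **Group comparison:** one-way fixed-effects ANOVA from sums of squares,
  run on rater means and, separately, on rater standard deviations, for TFS
  and TFA. Unbalanced groups (2/3/3 in the default panel) are handled by
  the standard unbalanced decomposition; no heteroscedasticity correction
  is applied. With three groups of eight raters the dfs are (2, 5). Post
  hoc: all pairwise pooled-variance two-sample t tests, Bonferroni-adjusted
  by the number of pairs (`p_adj = min(1, 3·p_raw)` for three groups).
* **Experience regression:** univariate OLS of rater means on planning
  years (all non-gold raters; df (1, 6) with eight) and on clinical years
  (only raters possessing the variable — biomedical engineers have none —
  df (1, 4) with six residents). A negative slope means improvement; the
  "improvement per year" is its magnitude. `F = t²`.
* **Degenerate inputs:** if every group has zero within-group variance
  (e.g. all raters reproduce gold exactly) the ANOVA is reported as a
  "no variability" note rather than a number; a constant outcome yields
  slope 0 with R² = 0.

Note: some published inter-rater analyses of this design report F(2, 7) for
three groups of eight raters; the classical one-way decomposition gives
within-group df = 5, which is what this package reports.

## Synthetic study generator

The generator defines the conditions under which the pipeline is validated.

* **Cases.** A fragment ensemble is produced by recursively cutting a
  16-gon prism (radius 12 mm, height 24 mm — the scale of a distal-radius
  metaphysis) with random planes: each cut splits the currently largest
  piece through a random interior point, rejecting cuts that leave a piece
  under 150 mm³. Fragments are convex plane-cut polytopes, not anatomical
  bone models; every downstream computation depends only on rigid geometry,
  so convexity costs no generality for validation purposes. Per-case
  fragment counts are drawn from the empirical distribution of the packaged
  demographics table (1–6 included fragments per case, mean 2.55). Gold
  poses are the assembled configuration; initial poses displace each
  fragment by 2–15 mm and 5–45°.
* **Rater error.** Each non-gold rater perturbs every gold pose by a
  translation of folded-normal magnitude `|N(μ_TFS, σ_TFS)|` in a uniform
  random direction plus a rotation of folded-normal angle about a uniform
  random axis *through the fragment center*. Rotating about the center
  keeps the simulated TFS and TFA independently controllable, mirroring the
  measure's independence property; the measured deviation equals the drawn
  pair exactly. Expected magnitudes decrease linearly in both experience
  variables and truncate at zero. Folded normals were chosen because the
  linear mean structure says nothing about the error distribution and
  magnitudes must be non-negative.
* **Calibration.** The model is parameterized by the univariate improvement
  slopes (defaults: TFS 0.943 mm/yr planning, 0.560 mm/yr clinical; TFA
  2.472°/yr planning, 1.394°/yr clinical) because univariate fits to one
  shared set of rater means are what such studies report. Planning and
  clinical years are strongly correlated across the default nine-rater
  panel, so using those slopes directly as additive coefficients would not
  reproduce them (omitted-variable bias ≈ −50% for the planning slope).
  `RaterErrorModel.calibrated_to(panel)` solves a 2×2 system in the panel's
  design moments for the internal additive coefficients such that
  noise-free univariate fits return the configured slopes exactly; the
  whole-study simulator calibrates by default.
* **Defaults without an external anchor.** Baselines (5 mm, 12°) were
  chosen so that the calibrated mean error stays positive for every panel
  rater (no truncation distortion) while junior raters commit errors of a
  few millimetres and ~10°, a realistic scale for manual intra-articular
  reduction planning; per-fragment noise (0.6 mm, 1.5°) gives visible
  within-rater spread without swamping the experience signal. These are
  free parameters of the simulation, not published values.

**What passing tests show.** Parameter recovery (mean recovered planning
slopes within ±20% over 50 replicates of 9 raters × 20 cases) demonstrates
that the pipeline is unbiased under the generator's assumptions:
index-corresponding vertices, exactly rigid plans, additive linear
experience structure, independent folded-normal errors. Real planning data
violate several of these (anatomical meshes, correlated errors across
fragments of a case, non-linear learning curves), so passing says the
*pipeline* is correct, not that the linear model is true of raters.

## Numerical choices

* Pose convention `v' = R·v + t`, right-handed axes, millimetres; rotation
  matrices accepted at 1e-6 orthonormality and re-projected (SVD) to 1e-12;
  reflections are rejected, never repaired. Quaternions are scalar-first
  and sign-canonicalized (w ≥ 0).
* Vertex order is the identity correspondence across poses of one fragment;
  duplicate vertices (STL) are deliberately not merged.
* Degeneracy gates: spatial rank from singular values at 1e-9 relative;
  OBB requires rank 3, registration rank 2.
* Determinism: every stochastic component takes a NumPy `Generator` or an
  integer seed; identical seeds give bit-identical cases and plans.

## Known limitations

* The OBB search is a high-quality heuristic, not the exact cubic
  algorithm; guarantees are empirical (brute-force-bounded in tests), and
  only the center — robust across near-minimal boxes — feeds the measure.
* Horn registration assumes known correspondences; there is no ICP
  fallback, no scaled/affine variant, and no vertex weighting.
* No articular-congruency or cartilage modelling: the measure scores rigid
  pose deviation only.
* The statistics layer implements the fixed-effects design it was built
  for; it does not provide ICC-type reliability coefficients or
  mixed-effects alternatives.
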
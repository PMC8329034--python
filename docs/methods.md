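# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `osteoplate`, and what the synthetic-data tests
do and do not demonstrate.

## Morphometric engine

**Standardization.** Columns are centered and scaled by the sample SD
(n−1 denominator); the means/SDs are stored so subjects and reconstructions
can be mapped back to physical units. Constant columns are rejected by
name.

**Adequacy tests.** KMO is computed from partial correlations obtained via
the inverse correlation matrix (pseudo-inverse with a warning when
singular); an exact identity matrix is rejected as 0/0. Bartlett's
statistic uses the standard χ² approximation
−(n−1−(2p+5)/6)·ln det R on p(p−1)/2 degrees of freedom and requires
n > p.

**Retention rule.** Components are ranked by eigenvalue; k is the smallest
count whose cumulative contribution rate (λ_k/p) reaches the threshold
(default 0.90, inclusive), then truncated so every retained eigenvalue is
strictly above the floor (default 0.5). When the two criteria conflict the
floor wins and a warning is attached. On the reference rates this yields
k = 4 (proximal) and k = 7 (distal).

**Varimax.** Pairwise Jacobi sweeps on the variables×components matrix,
Kaiser row-normalization on by default, convergence when the criterion
gains less than 1e−10 in a full sweep (cap 1000 sweeps). Orthogonality
guarantees communality conservation; tests check it to 1e−8.

**Composite score and classes.** The composite is the raw
contribution-rate-weighted sum of scores (a `normalized` flag divides by
the rate sum). Stratification is a tertile split — the field's simplest
reproducible choice where no clustering rule is specified — with ties
broken by subject order and earlier tertiles taking the extra subject.
ANOVA is classical one-way with the equal-variance assumption and no
multiple-testing correction, matching per-parameter significance
reporting.

**Reconstruction.** `x̂ = Aᵀs` is the orthogonal projection onto the span
of the retained components and is only accepted for raw (unit-row)
loadings; rotated loadings raise. With loadings quoted to three decimals
the projection identity holds to table precision (~1e−2); the exact 1e−8
identity is exercised with orthonormalized rows.

## Synthetic cohort

The reference statistics provide per-parameter means/SDs, block loading
matrices and contribution rates, but no subject-level data and no
cross-block correlations. The cohort emulator therefore:

- reconstructs each block correlation as R₀ = Σ_k (r_k·p)·v_k v_kᵀ with the
  residual variance 1−communality placed on the diagonal (reset to 1), then
  repairs to PSD by eigenvalue clipping (≥1e−8), re-symmetrization and
  diagonal re-unitization; the Frobenius repair delta is reported;
- assembles the 29-column matrix block-diagonally (proximal 9, shaft 3 as
  identity, distal 16, H_f independent) — unpublished cross-block
  correlations are set to zero;
- draws multivariate-normal subjects by Cholesky factorization and
  de-standardizes with the reference means/SDs.

The printed distal table's seventh column is a communality column (squared
norm ≈ 12, one entry 1.588 > 1), so the distal reconstruction uses the six
genuine columns; the remaining variance is diagonal noise. Consequence:
synthetic distal cohorts retain six components, not seven — the
seven-component retention result is checked against the printed rates
directly.

The diagonal reset raises the retained eigenvalues slightly above the
backbone values (each by roughly the mean residual variance), so cohort PCA
recovers the reference contribution rates to about one percentage point,
not exactly — the ±1.5 pp acceptance band reflects this plus sampling noise
at n = 5000. Skewness of real data (the reference cohort's −0.07 femoral
length skew) is deliberately not injected: synthetic cohorts are exactly
normal, and `validate_cohort` documents the difference. Passing tests on
these cohorts show the pipeline's internal consistency, not robustness to
real-world non-normality or measurement error.

## Synthetic femur surface

A smooth parametric proxy for the lateral proximal femur, not an anatomical
mesh: a generalized cylinder (radius D_fs/2, length H_fs) whose axis bows
laterally as a constant-curvature arc with total direction change
180°−A_fs (apex at mid-shaft — the smoothest realization of a mid-shaft
bend), plus a greater-trochanter bump modeled as a separable Gaussian
displacement: peak H_t1, axial σ = L_t/6 centered 0.267·L_t below the
proximal end, circumferential σ = L_t/3 of arc about the lateral line. The
trochanter's interior offset H_t2 is applied as a medial-side indentation
whose circumferential weight (σ = 0.30 rad about the medial line) vanishes
on the lateral contact strip (|θ| ≤ 1.45 rad): it shapes the interior
silhouette without touching the surface the plate contacts. Fit results on
this proxy demonstrate that the loft tracks a curved, bumped surface of the
right gross dimensions; they do not certify fit on real segmented femurs,
whose contact region carries ridge lines and cortical texture absent here.

## Plate derivation and component mapping

Default coefficients are calibrated once against the published Plate-A
instantiation and the reference mean femur, and are user-overridable:
α_W = 29/25.94, β = 39/65.86, local widths/heights as Plate-A fractions of
W and H_t1. α_L = 255/420.072: the plate spans the shaft, and since the
contact region is H_fs ≈ 269 mm long while the cohort varies H_f and H_fs
with comparable SDs, a mean plate length of 255 mm (within the Plate-A
calibration band) keeps end-to-end builds feasible across ±2 SD femurs
where 268 mm would leave a negative margin for below-mean femurs.

The published plate lists print a subset of the local parameters (and
print h₂ twice — the second occurrence is read as h₆, the only missing
index). Completion fills w₃, w₄, w₆ by linear interpolation between printed
neighbors, w₈ = w₀, and zero tail bump heights.

In the component mapping, scores are projected back to standardized bone
parameters per block. H_f and D_fs sit outside both PCA blocks, so they are
linked to their strongest reconstructed correlates: standardized H_f
follows the dominant proximal size component (p₁/√λ₁ — femoral length is
proportional to stature, which the size component captures), standardized
D_fs follows reconstructed D_fn. Zero scores reproduce the mean-shape plate
bit-exactly. The distal loading matrix is completed with a deterministic
seventh orthonormal row seeded on the femoral-surface-ratio axis (the
variable the seventh rotated component explains); it is flagged as a
synthetic completion in its provenance note.

Dimension-constraint ranges default to the derived value at the mean shape
± 3 linearly propagated SDs of the driving bone parameters; hierarchy
identities (L = l₁+l₂, W ≥ max wᵢ) are checked exactly. The audit function
returns violations as data; the derivation raises on them.

## Topology classification

Relation labels encode intersection count for boundary–internal pairs
(BI_0/BI_11/BI_21) and intersection position for internal–internal pairs
(II_11 endpoint–endpoint, II_12 endpoint–interior, II_13
interior–interior; multiple hits take the highest class). This digit
semantics is the unique simple encoding consistent with the published
eagle-plate matrix: ridges meet end-to-end (II_11), costals cross their
ridge mid-span (II_13), the neck costal passes through the ridge junction
(II_12), and costal ends lie on the boundary (BI_21).

Intersections are found on adaptive polylines: coarse sampling (default
384 points) with a candidate margin of the summed chord deviations,
Gauss/L-BFGS polish of each candidate in the two curve parameters, merging
of hits closer than max(100·tol, 1e−4) mm (tangential touches count once),
and a fixed-point walk that flags coincident stretches longer than
max(1000·tol, 1e−3) mm as degenerate overlaps. The endpoint tolerance is
1e−6 mm; the skeleton construction makes every genuine intersection an
exact shared interpolation node, so classification is robust at this
tolerance.

## Stations, loft and fit

Eleven stations carry the plate: tail tip, 0.55·l₁, a near-neck station at
l₁−0.4081·l₂, the neck l₁, six head stations at l₁+k·l₂/7, and the head
tip. Widths map as (w₀,w₀,w₁,w₂,w₃..w₈,w₈) — the two tail-most stations
share w₀ and the two head-most share w₈. The near-neck offset is tied to
the head span so that, in units of the trochanter-bump width, the axial
node layout is identical for every femur size; numerically this keeps the
axial interpolation error of the bump below ~0.07 mm across ±2 SD femurs.

The loft is a tensor-product cubic spline over a *rectangular* parameter
domain — stations × constant arc offsets spanning the full width W — with
the eagle outline acting as a trim curve (monotone PCHIP width function for
the shell and outline). Lofting the varying-width profiles directly would
couple the width function into the axial splines and make the long flat
tail span overshoot by millimetres; the trimmed rectangular loft removes
that coupling. Grid and profile points are surface samples, so a station's
bump height attribution is the measured apex lift; in free-space template
mode (no bone) profiles are parabolic arcs of apex height h_i.

Fit deviation is the minimum Euclidean distance of each contact point to
the patch: dense-sample nearest-neighbour seeding (240×33 samples,
k-d tree) followed by vectorized Gauss–Newton in (u, v) with step capping
and domain clamping (60 iterations); points whose interior projection
stalls keep the dense-sample distance and are counted as fallbacks.
Contact samples are drawn uniformly over the footprint (axial position ×
local width, linearly interpolated); 500 samples is the package's fixed
evaluation protocol.

The ±2 SD build sweep varies femurs jointly along the size mode (all
length parameters co-vary, the bend angle alternates sign) because
independent per-parameter extremes produce anatomically impossible femurs
— e.g. a +2 SD femur length with a −2 SD shaft length leaves no room for
the plate — which the footprint precondition rightly rejects.

**Solid and holes.** The outer surface offsets the undersurface along its
normals by a thickness field blending t₁→t₂ with a smoothstep over a neck
band 10 % of L wide (published instantiations all use t₁ = t₂, so the
blend is unexercised by fixtures but continuous by construction). The
shell stitches bottom, top and four side walls into a watertight mesh;
offsets that fold the surface (thickness beyond the local curvature
radius) raise. Tail holes sit on the tail ridge with clear rim spacing s₁
(center-to-center s₁+d₁, count floor((l₁−d₁)/(s₁+d₁))+1), head holes d₂/d₃
at the w₄ and w₆ stations; holes are exported as spec metadata (no CSG),
with axes along the outward surface normal. Meshes are written as binary
STL or ASCII OBJ/PLY, units mm, right-handed, bone axis +z, lateral +x.

## Problem sizes and determinism

Default problem sizes: cohorts of 5,000 for PCA recovery and 100,000 for
moment checks; 500 contact samples per fit report; 20 femurs in the build
sweep; 49 profile samples per station; 384-point coarse curve sampling.
Every stochastic step takes an explicit seed (`numpy.random.default_rng`);
builds, meshes and CLI outputs are bit-reproducible under a fixed seed.

## Known limitations

- Cross-block parameter correlations are unavailable and set to zero; the
  synthetic cohort cannot exhibit proximal–distal covariation.
- The distal block effectively carries six components (printed seventh
  column unusable); q₇ acts through a synthetic orthonormal completion.
- The bone proxy is smooth and unimodal; fracture geometry, cortical
  ridges and segmentation noise are out of scope.
- Hole placement records centers/axes/diameters but does not subtract hole
  cylinders from the shell mesh.
- The classification rule (tertiles) is one defensible reading of
  "three categories"; alternative stratifications can be plugged in at the
  composite-score level.
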
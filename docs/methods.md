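# Methods

`flowshape` represents a closed genus-0 surface — typically a segmented cell
membrane — by a single scalar field on the unit sphere and analyzes shapes
through the real spherical-harmonics (SH) coefficients of that field.  This
note records the model, the discretizations, the defaults and why, and what
the test fixtures do and do not establish.

## The curvature function on the sphere

A conformal map to the sphere preserves angles, so locally it only rotates
and uniformly scales the surface.  Under such a map the shape is fully
encoded (up to similarity) by the mean curvature together with the local
length distortion, combined into one field sampled per vertex:

    rho_i = H_i * sqrt(A_i / A'_i)

where `H_i` is the discrete mean curvature of the input mesh (normalized to
surface area 4π and centroid at the origin), `A_i` its barycentric vertex
area and `A'_i` the barycentric vertex area of the spherical image.  The
square root turns the area ratio into the length-distortion ratio.  Two
consequences used throughout as internal checks: `rho = 1` identically for
any round sphere (rho is a curvature half-density, hence scale invariant),
and the area-weighted sphere integral of `rho^2` equals the Willmore energy
`∫ H^2 dA` of the normalized input exactly, vertex by vertex.

Mean curvature comes from the cotangent Laplacian applied to positions (the
mean-curvature normal), signed by the outward vertex normal so convex
spheres have H > 0.  The pointwise division uses Meyer mixed Voronoi vertex
areas: barycentric lumping biases H by ~15% at the twelve valence-5 vertices
of subdivided icosahedra, while the Voronoi dual is accurate to ~1e-5 there.
Barycentric areas are retained everywhere an *integral* is needed (mass
matrices, the area ratio in rho, quadrature weights), where lumping bias
cancels or is harmless.

## Conformalized mean curvature flow (cMCF)

The spherical map is computed by implicit-Euler mean curvature flow with the
stiffness matrix frozen at the initial cotangent Laplacian and the lumped
mass matrix rebuilt each step — the "conformalized" modification that removes
neck-pinching and drives the map toward conformality.  Each step recenters
on the area-weighted centroid and rescales to unit RMS radius; converged
positions are hard-projected to the unit sphere.  No Möbius normalization is
applied; rotational freedom is absorbed downstream by the alignment step.

Convergence cannot be judged on raw sphericity `36π V²/A³`: a polyhedron
with chordal faces caps strictly below 1 (a 642-vertex icosphere reaches
only 0.99705).  The criterion used is sphericity *relative* to the same
connectivity radially projected onto the unit sphere, which tends to 1
exactly when all vertices approach a common sphere.  Defaults: step 0.05
(dimensionless after area normalization; the conformal quality is
indistinguishable from smaller steps on the ellipsoid benchmark, mean
quasi-conformal error 1.072 vs 1.071, at 5x fewer iterations), tolerance
5e-4 on relative sphericity (vertex radii within about 1% of a common
sphere), max 1500 iterations.  Very high area distortion (long protrusions)
makes the flow plateau and then degrade numerically as triangles collapse on
the sphere; the best map seen is tracked and returned, and the loop stops
after 30 iterations without improvement.

## SH decomposition

Real, orthonormal harmonics without the Condon–Shortley phase, coefficients
flat-ordered by (l ascending, m from −l to l); default band limit lmax = 24.
Fitting is iterative residual fitting (IRF): one area-weighted least-squares
problem per degree against the running residual, lowest degree first,
repeated (default 3 sweeps, tolerance 1e-6 on coefficient change; a few more
sweeps are worthwhile when coefficients are compared at 1e-6 accuracy, since
the discrete basis on a vertex grid is only approximately orthogonal).
Weights are the spherical vertex areas, which makes the discrete fit
approximate the L2 projection on the sphere; Parseval then holds to ~0.1%
between the coefficient norm and the quadrature integral of the synthesized
field on a 2562-vertex icosphere grid.

The sum of squared coefficients of rho is the (band-limited) total Willmore
energy W̃, minimized at 4π by round spheres.  The l = 0 term is included; the
pure deviation-from-sphere reading is W̃ − 4π.

## Spectral filters and protrusion detection

Smoothing multiplies degree l by `exp(−l(l+1)k/2)` (heat kernel), so the
realized spatial kernel has angular SD `sqrt(k)` radians — about 4° at the
default k = 0.005, as the acceptance script verifies by fitting a Gaussian
to the filtered image of a narrow cap.  The blob (protrusion) detector is
the Laplacian of Gaussian: the Laplace–Beltrami eigenvalue `−l(l+1)` times
the same Gaussian, sign-flipped so blob centers respond positively; it is
axially symmetric by construction and annihilates the constant.  Detection
thresholds the response at the spherical vertex positions and scores the
*original-mesh* area above threshold (area in physical units is the
meaningful proxy; measuring on the sphere would discount exactly the
features of interest, which the conformal map compresses).  The default
threshold is 3 robust SDs (1.4826·MAD) of the response; with a strong blob
present, a peak-relative threshold (e.g. 20% of the maximum response)
localizes more sharply because band-limit ringing of a strong curvature
spike can exceed the noise-level MAD far from the blob.

## Rotational alignment

Two curvature functions are aligned by maximizing their spherical
cross-correlation `C(R) = ∫ f(Rω) g(ω) dω` over SO(3).  In the SH domain C
separates: for each Euler angle β, the (α, γ) torus is a 2D Fourier series
of per-degree Wigner-d contractions, so the whole (2B)³ ZYZ grid costs one
small contraction per β plus a batched 2D FFT.  Wigner-d matrices are
evaluated by the explicit log-factorial sum (stable to the degrees used
here); real-coefficient rotation uses the complex Wigner matrix conjugated
by the real↔complex change of basis, giving orthogonal per-degree blocks
(power spectra are preserved to 1e-9).  The β grid starts at 0 so the
identity is an exact grid point — legitimate because β is explicit, not
transformed.  Default bandwidth B = 64 (≈2.8° resolution); no sub-grid
refinement.  A brute-force evaluator over explicit rotation lists serves as
the independent oracle; FFT values agree with it to machine precision.

The reported correlation r is normalized on the degree ≥ 1 coefficients
only: the constant component carries no orientation information and would
inflate r between any two near-spheres.  Pairwise alignment pre-smooths both
inputs with k = 0.005 (insensitive across k ∈ [0.001, 0.01]) but reports r
on the unsmoothed coefficients.  Groupwise alignment aligns everything to
the first shape, averages, re-targets, and repeats until the average moves
less than 1e-4.

## Reconstruction via the Dirac equation

Given a target rho on the sphere, a quaternion field λ is sought whose spin
transformation (rotate + scale each tangent plane) deforms the sphere into a
surface realizing rho.  Because arbitrary rho need not be integrable, the
Dirac equation `(D − rho) λ = 0` is relaxed to the eigenvalue problem
`(D − rho) λ = γ λ`, solved for the smallest |γ|; γ measures how far rho is
from realizability (γ ≈ 1 for the impossible rho = 0 on a sphere, ≈ 0 for
rho from a genuine shape).

Two discrete operators appear.  `dirac_operator` assembles the first-order
vertex operator by Galerkin-pairing the face-based Dirac
`(D_F λ)_f = −(1/2A_f) Σ e_i λ_i` with the hat basis and adding the
pointwise mean-curvature term; it is exactly quaternionic-Hermitian (real
4V×4V symmetric under the left-multiplication encoding) and maps the
constant field to the discrete mean curvature exactly.  Its direct
eigenproblem, however, exhibits spectral pollution (a spurious |γ| ≈ 0.04
mode on the unit sphere, whose true Dirac spectrum starts at 1), as lumped
first-order operators often do.  `solve_spin` therefore minimizes the
positive-semidefinite quadratic form `Σ_f A_f |(D_F λ) − ρ̃_f λ_f|²` with
corner-averaged potential ρ̃ = rho − H (the curvature *change* relative to
the sphere mesh) and corner-averaged λ_f — the normal equations of the spin
transformation, whose kernel is exactly the integrable case — and reports γ
as the square root of the smallest generalized eigenvalue (its sign is not
defined by the squared form).  Shift-invert at zero on the real symmetric
4V×4V system; eigen-residuals are ~1e-14.

New edge vectors use the endpoint-interpolated rule
`ẽ = ⅓ λ̄ᵢ e λᵢ + ⅙(λ̄ᵢ e λⱼ + λ̄ⱼ e λᵢ) + ⅓ λ̄ⱼ e λⱼ` and positions are
recovered by cotangent-weighted least squares on `vᵢ − vⱼ = ẽᵢⱼ` with one
vertex pinned and the mean moved to the origin afterwards.  Constant λ of
norm 1, unit norm, and norm √2 reproduce congruence, rotation and doubling
to machine precision.  λ is defined up to a global unit quaternion (a
rotation of the output) and sign; the sign is fixed by a non-negative
area-weighted mean scalar part, the rotation is absorbed by the rigid
alignment in the error metrics.  Reconstruction samples rho on a subdivided
icosahedron (default level 4, 2562 vertices) and rescales the output to
area 4π, since the relaxation leaves scale free.

Round trips (map → rho → fit → reconstruct) are scored by putting the
reconstruction in correspondence with the input *through the spherical
parameterization*: the input surface is resampled at the icosphere
directions via its cMCF map (KD-tree candidate faces, central-projection
barycentrics), a similarity Procrustes fit absorbs the reconstruction's
rotation/scale gauge, and RMSE plus symmetric Hausdorff distance (exact
point-to-triangle distances over dense area-weighted samples) are reported,
dimensionless under the area-4π normalization.  A rotation taken from the
B = 64 correlation grid instead of Procrustes would itself inject ~2-5%
RMSE, swamping the quantity being measured.

Self-consistent reconstruction error (rho from a mesh's own pipeline)
converges linearly in mesh size on the ellipsoid benchmark (γ 0.177 → 0.080
→ 0.043 over three subdivision levels) and then plateaus, consistent with a
representation limit rather than discretization.

## Shape statistics

Pairwise shape distance is d = 2(1 − r) with r from alignment, as printed;
the metrically conventional `sqrt(2(1 − r))` is available behind a flag.
Group comparison uses the Euclidean distance between mean coefficient
vectors (by Parseval, close to the L2 distance of mean curvature functions;
verified to 2% on band-limited fields).  The permutation test relabels
pre-aligned coefficient vectors — alignment happens once, jointly, before
testing, keeping the null exchangeable — enumerating all C(nA+nB, nB)
relabelings when feasible (a seeded uniform subsample including the identity
otherwise).  The identity labeling counts in the null, so p ≥ 1/N; for equal
group sizes the complementary relabeling duplicates the observed statistic,
so the attainable minimum is 2/N.  Bonferroni multiplicity is supplied by
the caller (test scope is experiment design, not library policy).  Effect
size is the observed statistic's distance from the null mean in null SDs.

Calibration: over 50 seeded same-generator 6+6 data sets the exhaustive
p-values are uniform to KS < 0.2.  Power: a single-coordinate l = 2 shift
must be large relative to the *statistic's* scale to register — the
169-dimensional norm dilutes coordinate shifts, so the demonstration injects
3x the null-mean distance (~20 null SDs of the statistic), which is detected
at the attainable minimum p with an effect above 3 SD.

## Synthetic data

The generators produce exactly reproducible, closed, genus-0 meshes:
icospheres (10·4^s + 2 vertices), anisotropically scaled ellipsoids, spheres
with radial protrusions, and band-limited random "cell-like" blobs whose
radial displacement field has seeded Gaussian SH coefficients over degrees
2..12 with power decaying as l^-2 (no net inflation or translation mode),
mimicking the front-loaded spectra of real cell shapes; amplitude default
0.15 gives mild, smooth lobes.  Protrusions displace a vertex-centered
angular cap along the radius by a C¹ bump `(1 − t²)²` reaching exactly
`length_ratio · radius` at an existing vertex (so the apex height is exact);
default width 0.3 rad makes a narrow finger for detector tests, while the
reconstruction stress sweep uses width 0.6 rad so the cap stays resolved by
the 2562-10242-vertex sphere samplings at every length.

What these fixtures do not emulate: microscopy noise, segmentation
artifacts, irregular real-mesh triangulations, contact flattening between
adjacent cells, or biological shape variability.  Passing tests establish
the correctness and the convergence behavior of the machinery, not
field performance on imaging data.

## Known limitations

* Long thin protrusions are the hard regime by construction: the conformal
  map compresses them onto tiny spherical caps where rho spikes (range
  ~[−6, 430] at twice-the-radius length).  At 2562-vertex reconstruction
  sampling, band-limit truncation can *reduce* measured error by flattening
  a spike the Dirac relaxation cannot realize anyway; at 10242 vertices the
  expected ordering (more harmonics never hurt) holds at every tested
  length.  Feeding raw rho beats the lmax-16 pipeline for lengths up to the
  radius but loses beyond ~1.5x, where the spike floors the relaxation
  (γ ≈ 0.25 even self-consistently); an area-corrected reconstruction is
  out of scope.
* The eigenvalue relaxation returns |γ| only (squared-form solve); the sign
  of γ is not meaningful here.
* The flow's stopping rule trades exactness for robustness on extreme
  distortion; relative-sphericity plateaus of 1e-4 to 3e-4 are expected for
  protrusion lengths 1-2x the radius.
* Alignment is global rotation only — no reflection, translation or
  non-rigid correspondence — and its resolution is the Euler grid (≈2.8° at
  B = 64) with no sub-grid polish by default.
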
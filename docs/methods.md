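# Methods

`armkin` decomposes movements of a flexible 3D appendage — the motivating
system is the octopus arm, a muscular hydrostat whose backbone is tracked
as a 3D midline curve per video frame — into elementary kinematic units,
classifies movements by their unit composition, and synthesizes new 3D
behaviors from unit combinations. This note records the models, the
numerical choices, and what the synthetic validation does and does not
show.

## Spatio-temporal representation

A movement is an ordered sequence of m backbone curves. Each curve is
resampled to n = 100 points at equal arclength spacing (linear
interpolation along the piecewise-linear input), anchored at its base
point, and normalized to unit arm length. Coordinates are then smoothed
with a cubic smoothing spline over arclength, and curvature and torsion
are estimated at every sample:

- **Curvature** κ at the middle of three successive points A, B, C is the
  inverse circumradius, κ = 4√(s(s−a)(s−b)(s−c))/(abc), with a, b, c the
  pairwise distances and s the semi-perimeter. Collinear triples give 0.
- **Torsion** τ at the middle of five successive points A…E is the angle
  between the osculating planes of triangles ABC and CDE divided by the
  distance between B and D. The plane angle is unoriented (arccos of the
  absolute normalized-normal dot product), so τ is **unsigned** and
  planar curves — including ones with inflections — give exactly 0.
  Near-collinear triangles (relative sine below 1e-9) are treated as
  straight sections and give 0; this also suppresses noise-driven spikes
  when re-extracting synthesized planar movements.

Profiles are undefined at 2 (κ) and 4 (τ) boundary samples; these
replicate the nearest interior value so every movement stays an n × n
matrix. Stacking the per-frame profiles and resampling the time axis from
m frames to n rows (same spline machinery, on time stamps normalized to
[0, 1]) yields a pair of **kinematic surfaces** κ(s, t), τ(s, t) on the
unit square: arm index s (0 = base, 1 = tip) by normalized time t. Both
estimators use only distances and angles, so the surfaces are invariant
under rigid motion of the input; arm-length normalization makes them
scale-free (κ and τ of the raw curve scale as 1/length). The distal 10%
of arm-index columns — tracked tips are noisy and analyzed separately —
is flat-filled from the last retained column by default
(`tip_exclude_fraction = 0.1`).

### Smoothing parameter

The spline minimizes p·Σ|y_j − f(x_j)|² + (1−p)·λ₀·∫|f″|², with de
Boor's spacing normalization λ₀ = h̄³/6 (h̄ = mean site spacing on the
unit-normalized axis). This keeps the meaning of p independent of the
sample count: the fidelity/smoothness transition sits near p ≈ 0.5, p = 1
interpolates, p = 0 returns the least-squares line. Without the
normalization, p = 0.99 at n = 100 sites on [0, 1] sits deep in the
flattening regime and erases real bends (a unit-length helix loses ~95%
of its curvature). Default p = 0.99: light jitter removal that leaves
closed-form test curves intact to better than 1%.

## Surface decomposition into Gaussian units

A surface is approximated as z(s, t) = Σᵢ wᵢ·g[μᵢ, Σᵢ](s, t), a weighted
sum of bivariate normal densities. Each Gaussian is a candidate
**kinematic unit**: a localized bend/twist episode on an arm section over
a time interval, with interpretable features — center μ (where/when),
shape λ_max/λ_min, size √(λ_max·λ_min), orientation (angle of the major
axis to the arm-index axis, folded into [0°, 90°]; 0 by convention for
isotropic Σ), and weight w.

Because the data is a surface rather than a sample, the fit is **weighted
EM**: every grid cell is an observation at its (s, t) coordinates with
mass proportional to the (nonnegative, clipped) cell value. Masses are
normalized to sum to n_obs (the number of positive cells) so the weighted
log-likelihood L is on the scale of n_obs effective observations.
Mixture proportions are rescaled by the total surface mass Z (grid sum ×
cell area) to give weights in value units; Σwᵢ = Z holds exactly.

Numerical choices: k-means++ seeding on mass-weighted cells; covariance
eigenvalue floor 1e-6 (prevents collapse onto single cells); starved
components reseeded at a random mass-weighted cell; convergence when the
relative log-likelihood change drops below 1e-8 (max 500 iterations);
deterministic given a seed. The number of Gaussians minimizes
BIC = −2L + d·log(n_obs) with d = 6k − 1 free parameters (k weights with
a fixed total, 2k means, 3k covariances), best of 5 seeded starts per k,
ties to the smaller k.

## Clustering units into a vocabulary

Units pooled across movements (curvature and torsion separately) are
clustered with k-means under a **weighted Euclidean distance**: the
Euclidean distance is computed per enabled feature, divided by that
feature's sample standard deviation (for the 2D center, the RMS of the
two coordinate standard deviations), and the per-feature distances are
combined by their quadrature (root-mean-square) average. This is a scaled
Euclidean norm on the stacked feature space, so Lloyd's mean-centroid
update exactly minimizes the summed squared distance, and within-cluster
dispersion separates across features. (An arithmetic mean of the
component distances was considered and rejected: it makes within-cluster
dispersion behave one-dimensionally, and the gap statistic then cannot
stop at the planted cluster count.) The default feature subset is
{center, shape, weight}; {center, shape, size, orientation} is available
as `GEOMETRIC_FEATURES`.

k-means runs a batch (Lloyd) phase followed by single-point reassignment
passes, accepting only objective-decreasing updates, best of 10 seeded
starts; empty clusters reseed at the farthest point. The cluster count
is the smallest k at a local maximum of the gap statistic
Gap(k) = (1/B)Σ_b log(W*_kb) − log(W_k), with B = 50 reference sets drawn
uniformly over the per-feature bounding box of the data and clustered
with the same metric and (data-derived) scales. W is the summed squared
point-to-centroid distance. Cluster centroids map back to representative
Gaussians by element-wise parameter averaging (convexity preserves
positive definiteness); a medoid mode is available. The centroid units
form the **kinematic-unit vocabulary**.

## Movement encoding and prototypes

With the vocabulary frozen, each movement is encoded as the nonnegative
weight vector w = [{wᵢᶜ}, {wⱼᵀ}] solving min‖Σ wᵢ gᵢ − z‖² per quantity
by nonnegative least squares on the fixed centroid basis (means and
covariances frozen); the per-surface residual RMSE reports what the
vocabulary cannot express. (The alternative of pooling a movement's own
fitted Gaussians' weights onto their nearest centroids is provided as
`pool_encoding`.) k-means on the weight rows — plain Euclidean, the
weights share units — groups movements into sub-groups; cluster means are
the **movement prototypes**, rendered back into surface pairs through the
vocabulary. New movements match to the nearest prototype pattern.

## Synthesis

A 3D configuration is reconstructed from κ(s), τ(s) profiles by
integrating the Frenet–Serret system r′ = T, T′ = κN, N′ = −κT + τB,
B′ = −τN with RK4 (step = the arclength grid spacing, coefficients
linearly interpolated at half steps) and Gram–Schmidt
re-orthonormalization of the frame after every step, preserving
handedness. Straight sections (κ = 0) advance the frame by parallel
transport, which the system does naturally — and exactly in floating
point, so curvature-only behaviors are planar to machine precision. A
behavior couples a curvature unit with at most one torsion unit: each
time slice of their rendered surfaces is reconstructed with a fixed base
position and frame. Unsigned torsion is interpreted as positive τ
(chirality fixed right-handed) — a documented limitation of the unsigned
representation. n_C curvature and n_T torsion units span n_C·(n_T + 1)
behaviors (torsion alone leaves a straight arm straight and contributes
none).

## Synthetic data and what the tests show

No tracked recordings ship with the package; `simdata` plants known
structure at the scale of real recordings (n = 100 points, tens of frames
per movement, tens of movements per group):

- `gen_surface` / `gen_movement`: surfaces from planted units plus
  clipped Gaussian observation noise, integrated into 3D curve sequences
  frame by frame (optional 3D point jitter stresses the spline stage).
- `four_gaussian_units`: a 4-Gaussian extension-like curvature surface
  (proximal fixed bend, two travelling-bend episodes, a distal late
  episode; pairwise center separations > 6σ).
- `gen_unit_clusters`: well-separated planted clusters of units in
  feature space, with within-cluster noise kept comparable across
  clusters and features (center sd 0.012, weight sd 0.03, additive
  shape-ratio sd 0.05) so separation-to-spread stays above 6σ.
- `extension_vocabulary` / `extension_weight_patterns`: a representative
  3-curvature/3-torsion vocabulary and three prototype weight patterns.
  `gen_classification_set` draws each movement's weights as its pattern
  plus isotropic N(0, 0.05) jitter (sub-groups share similar, not
  identical, combinations) and adds surface noise at 10% of each
  movement's peak by default.
- Analytic `fixtures`: line, circle arcs (κ = 1/r), the (a = 1, b = 0.5)
  helix (κ = 0.8, τ = 0.4), a planar S-curve, a drifting-pitch helix
  sequence for invariance checks.

Passing plant-and-recover tests show that the estimators and the
selection rules recover structure **of the kind they assume** —
smooth Gaussian-composed surfaces, isotropic well-separated feature
clusters — at realistic noise. They do not certify performance on real
tracked arms, where midline-extraction artifacts, signed torsion
(handedness), arm elongation during movement, and non-Gaussian surface
topography all occur. Two further caveats: the weight-jitter magnitude in
the classification generator controls how informative the gap statistic
is (near-duplicate weight vectors make log-dispersion degenerate), and
the literal local-maximum gap rule is noise-sensitive when the gap curve
is flat beyond the true k — single unlucky draws can elect one extra
cluster.

## Degenerate inputs and tie-breaks

Curves with coincident consecutive points are rejected; collinear triples
give κ = 0; degenerate torsion windows give 0 with a warning; zero-mass
surfaces decompose to an empty unit list with a warning; requesting more
Gaussians than positive cells, or more clusters than points, is an error.
The bend point (arm index of maximal curvature, floor 1e-3) breaks ties
to the most proximal maximum; prototype matching breaks ties to the
lowest label; BIC ties go to the smaller k. Movement sub-group and
cluster labels are 0-based.

## Problem sizes used in validation

The shipped validation runs at the study scale it emulates: 100 × 100
surfaces; 10 seeds for BIC plant-and-recover (k ≤ 6, 5 starts each);
20 seeds × (60 units, B = 50 references) for gap recovery; 100 random
rigid motions of a 15-frame sequence; 30 movements (3 sub-groups) for
prototype recovery. The full suite completes in a few minutes on one
core.
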
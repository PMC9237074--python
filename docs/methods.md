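# Methods

This note documents the models and procedures `scalpmap` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Marker detection

Per-vertex RGB colors are converted to HSV (standard hexcone, hue in [0,1))
and thresholded by per-color HSV boxes. Hue intervals may wrap through zero
(`h_lo > h_hi`); all bounds are inclusive. The package ships default ranges
for red, green, blue and yellow; real acquisitions should supply their own,
since marker paint and lighting shift the usable boxes.

Selected nodes are grouped by single linkage: two nodes join the same marker
iff some chain of nodes at pairwise distance strictly less than
`link_dist_mm` connects them. The default, 3 mm, is the marker diameter —
the pairwise rule "closer than the marker size ⇒ same marker" is exactly
graph connectivity, which is why single linkage (and not k-means or DBSCAN)
is the right primitive here. Clusters with fewer than `min_cluster_nodes`
(default 3) members are discarded as speckle: isolated miscolored vertices
are common on photogrammetric meshes. Each surviving cluster's position is
the unweighted mean of its member coordinates (no per-node weights are
defined), then optionally snapped to the nearest scalp node, with ties broken
by lowest vertex index for determinism.

Detection is rigid-invariant by construction (all operations are on
distances and means), which the tests verify to 1e-6 mm.

## Mesh conditioning

* **Box-grid downsampling** partitions space into cubic boxes of a single
  edge length and replaces each occupied box by the mean of its vertices.
  The edge length is found by bisection (≤ 60 iterations) so the output
  count lands within ±10 % of the target; the targets used by the
  registration pipeline are ~3000 (affine) and ~9000 (non-rigid) nodes.
  Output is a point set; connectivity is not preserved.
* **Low-pass smoothing** is the two-factor Taubin scheme: alternating
  Laplacian steps with weights λ=0.5 (shrink) and −ν, ν=0.53 (inflate),
  10 iterations by default. It is volume-preserving to well under 2 % on a
  closed mesh, which is the reason this smoother (rather than plain
  Laplacian shrinkage) is used on head surfaces.
* **Nasion cut**: registration is biased by nose-slope differences, so both
  surfaces are cut with an axial plane 10 mm below the nasion before CPD.
  "Axial" is defined by the head frame built from landmarks: origin at the
  LPA/RPA midpoint, right axis along RPA−LPA, anterior axis the
  orthogonalized nasion direction, superior axis their cross product. The
  10 mm offset is a package default (config-exposed), chosen so the plane
  clears the brow while removing the nose on adult-sized heads.

Because the downsampled product has no faces, smoothing runs on the full
mesh *before* downsampling; the reverse order would have nothing to operate
on.

## Registration

**Landmark fits.** The rigid fit is orthogonal Procrustes via SVD with the
determinant sign corrected, so a reflection is never returned; it uses
{nasion, Cz, LPA, RPA} — deliberately omitting the inion, the least reliable
landmark. The affine fit solves the 15-equation/12-unknown least-squares
system over all five landmarks and raises on coplanar configurations.

**ICP** alternates nearest-vertex correspondence with a Procrustes update,
re-fitted from the original moving set so the returned transform is already
composed. Point-to-vertex (not point-to-plane) correspondences keep the
update exactly testable. The recorded mean correspondence distance is
non-increasing; iteration stops when it improves by less than `tol_mm`
(default 1e-4 mm) or at `max_iter` (100), with a convergence flag either way.

**CPD.** The moving set Y is treated as K Gaussian centroids with common
variance σ², mixed with a uniform outlier component of weight ω. The E-step
computes posteriors P(k|n) ∝ exp(−‖xₙ−T(yₖ)‖²/2σ²) normalized including the
outlier term c = (2πσ²)^{3/2}·ω/(1−ω)·K/N. The affine M-step is a weighted
least-squares update of (A, t) and σ²; the non-rigid M-step solves
(diag(P1)G + λσ²I)W = PX − diag(P1)Y₀ with Gaussian kernel
G_ij = exp(−‖y₀ᵢ−y₀ⱼ‖²/2β²). Parameters: ω (expected outlier/noise
fraction, default 0.4), λ (smoothness trade-off, default 5), β (kernel
width, default 4 in normalized units). Numerical choices:

* both sets are jointly centered and scaled to unit RMS before EM; the
  joint (rather than per-set) normalization lets the fitted non-rigid warp
  de-normalize exactly into the mm-space form
  x ↦ x + Σₖ exp(−‖x−y₀ₖ‖²/2β'²)·wₖ with β' = β·scale. Sets are rigidly
  pre-aligned beforehand, so joint normalization loses nothing;
* σ² is initialized from the mean pairwise squared distance between the
  sets, clamped below at 1e-8 (underflow stops EM);
* EM stops when the negative log-likelihood (plus λ/2·tr(WᵀGW) in the
  non-rigid mode) changes by less than 1e-6 relative, or at 150 iterations.

The full pipeline, per method: *landmarks* — affine from the five
landmarks, applied to sensors. *cpd_affine / cpd_nonrigid* — smooth the
individual mesh, downsample both surfaces (~3000 / ~9000), rigid
pre-alignment from {nasion, Cz, LPA, RPA}, cut both below the nasion, CPD,
push sensors through the composed map, snap to the nearest atlas node.

## Evaluation

Localization error is the per-sensor Euclidean distance in mm, summarized
by median and MAD (raw, not normal-consistent). Scalar-field regions use a
strict threshold (value > frac·max, default 0.8); the field peak is the
value-weighted centroid of the region. Dice is 2|A∩B|/(|A|+|B|); both-empty
is an error, not 0. Method comparisons pivot the error table to
(subject, sensor) pairs and run paired two-sided Wilcoxon signed-rank tests
on every method pair — zero differences dropped, exact null for ≤ 25
non-zero pairs, otherwise a continuity-corrected normal approximation; the
degenerate all-zero case reports p = 1 by convention — followed by
Benjamini–Hochberg adjustment across pairs. Detected markers are matched to
ground-truth layouts by minimum-total-distance (Hungarian) assignment
before scoring, since detection labels carry colors, not layout names.

## Synthetic data

The phantom is an ellipsoid (semi-axes 98 × 134 × 110 mm) modulated by
deterministic Gaussian angular bumps — nose, brow ridge, occipital
protrusion and two slightly asymmetric parietal features, a few mm each.
The features matter: a pure ellipsoid is affinely self-similar (S₂RS₁⁻¹
maps one ellipsoid onto another for every rotation R), so a planted affine
would be unidentifiable from surface registration, and real heads are not
ellipsoids. Landmarks sit at the anatomical extremes of the surface; layout
positions are built from arc fractions on the unit sphere (midline
meridian, the 10 % ring, and interior coronal rows at steps 0.2 / 0.1 /
0.05) and mapped to the surface. This construction yields 21 / 69 / 261
positions for 10-20 / 10-10 / 10-5 — the module's own layout table is the
source of truth for these counts, since published layout variants differ.
Markers are painted as disks (vertex within radius of the disk center);
requesting a layout denser than the marker size, or a mesh too coarse to
put ≥ 3 vertices under a disk, raises a layout-density error.

Subjects derive from the atlas by (in order) a random affine — per-axis
scales in [0.93, 1.07], rotation ≤ 15°, shears ≤ 0.08, about the head
centroid with no translation — a smooth non-rigid field (12 Gaussian
kernels, 40 mm width, amplitudes ≤ 4 mm), and optional per-vertex noise
applied to the mesh only. Landmarks and sensors ride the noise-free map, so
the atlas correspondence is exact to 1e-9 mm. Every stage draws from its own
named substream of the seed, so adding a stage never perturbs earlier draws.

`measure_landmarks` emulates the identification step real pipelines
require: isotropic perturbation (default σ = 3 mm, reflecting the several-mm
variability of manual cranial-landmark identification) followed by a snap
to the nearest mesh node. Fluence-like fields are isotropic Gaussians of
Euclidean distance from a center vertex (geodesic distance would differ
only at widths comparable to surface curvature; at the 15–20 mm widths used
here the difference is negligible on a scalp-sized surface).

What the generator does *not* emulate: photogrammetric reconstruction
artifacts (holes, texture bleeding, scale drift), hair and cap geometry,
true anatomical variability beyond smooth low-order deformation, and
physics-based photon transport (fields are fixtures for the metric code,
not simulations). Passing tests therefore demonstrate the correctness of
the operators and the qualitative behavior of the pipeline, not in-vivo
accuracy levels.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to keep full runs
in the minutes range on one CPU: atlas meshes at icosphere subdivision 6
(~28k vertices after the lower cut; ~2 mm edges), marker-recovery phantoms
at subdivision 7 (~1 mm edges), CPD affine at ~3000 points (the production
target), CPD non-rigid at ~800–1200 points standing in for the ~9000-node
production setting (the dense solve is cubic in the control-point count),
and 3–5 synthetic subjects per study.

## Known limitations

* CPD affine between two *independently* downsampled ~3000-point samplings
  of smooth cut surfaces exhibits a 2–4 mm transform bias relative to the
  surface-optimal affine (the least-squares affine on true
  correspondences): the EM optimum of the density-matching objective at
  this sampling density genuinely sits there — restarting EM at the planted
  truth returns to it, and it persists for ω ∈ {0, 0.1, 0.4} and for a
  dense fixed set. This is a property of the estimator on this class of
  geometry, not a convergence failure; with exact-correspondence inputs the
  implementation recovers planted transforms to ~1e-11 mm.
* Consequently, on synthetic subjects whose deformation is mild
  (DeformationSpec defaults) and whose landmarks are identified to ~3 mm,
  the landmark-only affine is competitive with — often better than — the
  surface-based CPD mapping. The in-vivo advantage of surface-based
  registration rests on landmark and anatomical variability larger than
  these synthetic conditions produce; the package reports whatever the
  configured conditions yield.
* Only per-vertex color is supported (no texture atlases); meshes are
  assumed to be in mm with no axis convention beyond what landmarks define.
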
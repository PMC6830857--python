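# Methods

This note documents the models and procedures implemented in `gastro3d`,
the assumptions behind them, the parameters that matter, the numerical
choices made where the design was open, and the known limitations —
particularly what the synthetic-scene tests do and do not establish about
real endoscope data.

## Problem setting

A monocular endoscope video of a dye-sprayed stomach is fed to an external
incremental structure-from-motion (SfM) tool, which returns a sparse model:
per-frame camera poses, intrinsics, and a 3D point cloud in which each point
carries a *track* of the 2D observations that triangulated it.  Scene units
are arbitrary (monocular SfM cannot resolve metric scale; the package never
attempts to).  The cloud is contaminated by two outlier families — isolated
points scattered far from the organ (spurious feature matches) and
near-surface points displaced by triangulation error — and the frame stream
contains runs of (near-)identical frames produced by the capture hardware.

## Duplicated-frame removal

Frames `I_t`, `I_{t+1}` are compared by the fraction of pixels whose
absolute intensity difference exceeds `zero_tolerance` (default 0, i.e.
strictly non-zero differences; a pixel of a multi-channel frame differs if
*any* channel differs).  The scan keeps the current reference, drops
successors while the ratio is `< φ`, and promotes the first frame with
ratio `≥ φ` to be the new reference.  The first frame is always kept, and
the pass is idempotent.  Operating value `φ = 0.6`; comparisons run on raw
uint8 intensities with no normalisation.  `zero_tolerance` exists because
real sensors add noise that makes exact-duplicate detection fragile; the
default matches exact duplication, which is also what the synthetic fixture
plants.  The duplicate test itself is channel-agnostic; the CLI deduplicates
single-channel sequences after channel separation, which is where
duplication is observed in practice.

## Outlier-removal cascade

Stage order and statistics (defaults `A = 0.05`, `M = 80`, `B = 5`,
neighbour cap 100):

1. **Isolated filter.** `r` is the bounding-box diagonal of the input cloud
   P.  A point is removed when its nearest-neighbour distance exceeds
   `A·r`.  The pass is single-shot: the neighbour search runs over the
   input cloud and removals do not cascade.  `r` is then recomputed on the
   survivors P′.
2. **Neighbourhood census.** Each survivor gathers the neighbours within
   radius `r` of itself, capped at the 100 nearest.  Points with fewer than
   `M` neighbours are removed.  Note that a radius equal to the whole
   cloud's diagonal makes nearly every point an in-radius neighbour, so the
   cap of 100 nearest dominates in practice; the radius is implemented
   literally with a `radius_scale` knob (default 1.0) for users who want a
   genuinely local census.
3. **Local plane filter.** For each censused point a plane is fitted to its
   local set by RANSAC over random point triples; the point's unsigned
   distance `D_i` to its own best plane is recorded; after all fits, points
   with `D_i` strictly above the mean of all recorded `D` are removed
   (strict, so an exactly planar cloud loses nothing).  The mean is computed
   once, over census survivors only — census failures never receive a
   distance.
4. **Smooth-mesh filter.** A deliberately low-resolution surface is
   reconstructed from the survivors (implicit meshing at depth 5, i.e. a
   32³ field grid); every point's unsigned point-to-mesh distance is
   computed; σ is the population standard deviation of that distribution;
   points farther than `B·max(σ, σ_floor)` are removed.  The floor
   (`1e-12·r` by default) prevents total removal of a cloud lying exactly
   on its own smooth mesh, where σ would vanish.

### RANSAC details

The "best plane" criterion is inlier-count maximisation at threshold
`ε = 0.01 ×` the local set's bounding-box diagonal — a scale-free choice
that requires no absolute noise estimate.  Ties break by the smaller sum of
inlier distances, then by draw order; all tie-breaks in the cascade
(including equidistant neighbours at the cap boundary, resolved to the
lowest point index) are deterministic, so a fixed `ransac_seed` reproduces
the removal sets bit for bit.  The iteration budget is 200 triples per
point; degenerate (collinear) triples are rejected but consume budget.
When the budget covers all `C(n,3)` triples the implementation enumerates
them deterministically instead of sampling — this is the mode the oracle
tests exercise against brute-force enumeration.  Per-point random streams
derive from one seed via independent spawned sequences.

### Aggressiveness of the above-average rule

The stage-3 cut "remove if `D_i` is above the mean" deserves a caveat.  On
a cloud whose distance statistic is continuously distributed — e.g. Gaussian
surface noise, giving a half-normal `D` — the fraction of *good* points
above the mean is 40–45% regardless of the noise scale, because the
statistic is scale-free.  With planted far outliers the mean shifts up and
the collateral loss drops (about 20–30% of inliers on the reference scene),
but it never approaches zero.  The rule therefore buys a final cloud that is
essentially free of near-surface outliers (kept-cloud purity ≈ 1.0 on the
reference scene) at a real cost in density, which the downstream implicit
meshing tolerates.  This is a property of the algorithm, not of the
implementation: the package's no-harm acceptance test (≥ 95% retention on an
outlier-free cloud) documents the behaviour by failing honestly — measured
retention is ≈ 0.57 — and is intentionally left that way rather than
weakening either the rule or the test.

## Normal estimation, orientation, meshing

Per-point normals are the smallest-eigenvalue eigenvectors of the 100-NN
covariance (batched `eigh`; eigenvector sign is arbitrary at this stage and
the solver's deterministic ordering resolves isotropic ties).  Orientation
uses the camera poses: each tracked point's normal is flipped to satisfy
`n · (c̄ − p) ≥ 0`, where `c̄` is the mean centre of its observing cameras;
exactly orthogonal normals are kept unflipped; untracked points fall back to
the globally nearest camera centre.  Since the endoscope travels inside the
cavity, oriented normals face the lumen.  Smoothing replaces each normal by
the renormalised mean over its `k_smooth` = 10 nearest neighbours
(including itself; `k_smooth = 1` is the identity and a uniform field is a
fixed point); a cancelled mean falls back to the original normal.

Meshing contours the zero level set of a signed distance field
`f(x) = Σ w_j · n_j·(x − p_j) / Σ w_j` (inverse-distance weights over the
8 nearest oriented points) sampled on a `2^depth` grid over the padded
bounding box, using marching cubes.  `depth` controls resolution the way an
octree depth does: depth 5 yields the "very smooth" surface used by cleaning
stage 4, depth 6–8 resolves finer anatomy.  On the 2000-point analytic
sphere the depth-6 mesh sits within 0.4% RMS of the true radius and vertex
count grows monotonically with depth (measured by the acceptance script).
A field with no zero crossing (inconsistent normals, degenerate input)
raises rather than returning a broken mesh.

## Texturing and localization

Per-vertex color transfer ranks candidate cameras by
`score = cosθ / (1 + d / r_mesh)` — dimensionless and monotone in both of
the stated criteria, "closest" and "most orthogonal" — where θ is the angle
between the surface normal and the direction to the camera, d the distance,
and `r_mesh` the mesh bounding-box diagonal.  Visibility requires the point
in front of the camera, projecting inside the image, and the camera on the
normal side; self-occlusion is not ray-tested by default (a single cavity
seen from inside has limited self-occlusion).  Projection uses the pinhole
part of the intrinsics: frames are assumed undistorted by the upstream
calibration tool, and full UV texture-atlas packing is out of scope — the
per-vertex simplification is deliberate.

Frame localization casts a configurable grid of pixel-centre rays (default
32×32, not per-pixel: a footprint visualisation does not need full
resolution) through the camera model and records first hits on the mesh
(Möller–Trumbore, vectorised); rays may start inside the mesh.  Retrieval
ranks frames by Euclidean descriptor distance, reference first at distance
zero, ties by frame index.  The default descriptor — grayscale 16×16
thumbnail, mean-subtracted, L2-normalised — is deterministic,
brightness-scale invariant and dependency-free; it stands where a
place-recognition CNN would in a production system, and externally computed
CNN vectors can be substituted through the descriptor registry or a JSON
descriptor bank without changing the ranking contract.

## Synthetic scenes

The generator produces a star-shaped cavity `R(θ,φ) = r_ellipsoid · (1 +
a·b(θ,φ))` (semi-axes (1.0, 0.75, 0.6) — stomach-like proportions; bump
amplitude 0.08 with 12 Gaussian bumps as rugae-like relief).  The radial
parameterisation gives an exact signed distance, so every planted label is
verifiable: inliers are surface samples with radial Gaussian noise
(σ = 0.01, about 0.4% of the cloud extent — typical bundle-adjusted
triangulation jitter); near outliers sit at radial offsets of 5–15σ; and
isolated outliers are rejection-sampled to lie farther than `0.05·r` from
every other point, with the contract re-verified exhaustively at generation
time.  Cameras ride a smooth interior loop with cycling pitch and observe
their nearest in-view points; any point seen by fewer than two cameras is
assigned to the two best-facing ones (idealised visibility — the tracks
exercise bookkeeping and orientation, not photometrics).  Frame fixtures are
procedural uint8 noise with bit-exact duplicate runs and an exactly
controlled changed-pixel fraction between distinct frames.

What passing on these scenes shows: the filters implement their definitions
exactly (oracle equivalence), the cascade removes planted contamination of
the stated geometry completely, and the geometry/IO layers are exact.  What
it does not show: robustness to real SfM error statistics (heavy-tailed,
anisotropic, track-length dependent — the synthetic noise is radial
Gaussian), to photometric artifacts (the procedural frames have no imaging
model), or to anatomy outside the star-shaped assumption (a real stomach
with a deep fundus fold is not single-valued in radius).  Problem sizes in
the tests and acceptance script (5000-inlier scenes, 2000-point spheres,
500-frame sequences) are the package's reference conditions, chosen so the
full suite runs in well under a minute of compute per scene.

## Other numerical choices

* Point-to-mesh distances prune candidate triangles with a kd-tree on
  centroids (32 candidates) and then evaluate exact point-triangle
  distances; adequate for the smooth, uniformly triangulated meshes the
  package produces.
* σ in stage 4 is the population standard deviation of the unsigned
  distances, not a mean-centred absolute deviation; the point-to-mesh
  distance is unsigned.
* Sparse-model text is written with 17 significant digits, so write → read
  round-trips are exact at double precision; PLY binary round-trips are
  bitwise.
* Quaternions are stored `(w, x, y, z)`, world-to-camera, unit to 1e-9;
  pixel coordinates pass through verbatim with a top-left origin.
* Degenerate inputs fail loudly: empty clouds, all-collinear local sets,
  zero registered frames, mixed frame dimensions and broken
  observation/track cross-links all raise typed errors.

## Limitations

* The neighbourhood radius of the census stage is the literal bounding-box
  diagonal (see above); the `radius_scale` knob is provided but 1.0 is the
  faithful default.
* The stage-3 rule's density cost on clean data is inherent (see
  "Aggressiveness").
* Meshing is implicit-field reconstruction, not screened Poisson; for very
  non-uniform clouds a Poisson solver's adaptive octree would degrade more
  gracefully than a uniform grid.
* Color transfer is per-vertex; no seam-aware texture atlas is produced.
* Local reconstruction around a reference frame is orchestration only: the
  package selects and exports the frame set, and the external SfM tool does
  the rest.
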
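# Methods

`bonetrack` recovers the six-degree-of-freedom poses of individual bones
from pairs of calibrated X-ray fluoroscopy images by matching the
occluding contours of triangle-mesh bone models to edge-enhanced images.
This note records the model, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Projection model and calibration

Each view is an ideal point-source projection onto a flat panel: a 3x4
homogeneous matrix `P` maps world coordinates (mm) to pixels, up to
scale. `P` is estimated from >= 6 non-coplanar 3D-2D marker
correspondences by the direct linear transformation (DLT): the
homogeneous linear system is solved by SVD under a unit-norm constraint
(11 free parameters). Both point sets are centred and isotropically
scaled first (Hartley normalisation); without it the design matrix is
badly conditioned at full-panel pixel scales. Coplanarity of the 3D
markers is detected from the singular values of the centred marker cloud
and rejected, since planar DLT is rank-deficient.

Two quasi-orthogonal views form a rig. Points seen in both views are
reconstructed by linear DLT triangulation of the two back-projected
rays; the shortest gap between the rays (miss distance) is reported as a
per-point quality measure. *Calibration error* is defined as the 3D
Euclidean error of triangulated markers against the known phantom
geometry — the millimetre unit of the published figure identifies it as
a reconstruction error, not a pixel residual; this reading is a
documented choice.

Trapezoidal (keystone) distortion from imperfect detector orthogonality
is modelled as a plane homography applied to the raw image (bilinear
resampling under the inverse map). Radial lens-type distortion is out of
scope: flat panels do not need it.

Pixel convention everywhere: origin at the centre of the top-left pixel,
u rightward along columns, v downward along rows, 0-based.

## Bone models, frames and poses

Bones are triangle surface meshes in mm with named landmarks. The
anatomical frame has its origin at the *area-weighted surface centroid*
(well defined even for slightly open meshes) and axes built from three
landmarks by Gram-Schmidt: x (anteroposterior) from the first two, z
(dorsoplantar) along the normal of the landmark plane, y (mediolateral)
completing the right-handed triad.

Orientation is parameterised by intrinsic y-x-z Euler angles, in
degrees: phi about y (plantarflexion-dorsiflexion), theta about x
(inversion-eversion), psi about z (adduction-abduction), i.e.
`R = R_y(phi) R_x(theta) R_z(psi)`. Whether the published sequence is
intrinsic or extrinsic is not decidable from its description; intrinsic
is chosen because the anatomical reading (rotation about the bone's own
mediolateral axis) demands body-fixed axes, and the convention is
documented so results remain reinterpretable. The inverse map takes
theta in [-90, 90] deg; at gimbal lock psi is set to 0 and phi absorbs
the free rotation, with a warning.

## The edge chain

For a measured (fluoroscopic) image the binary edge map `F` is:
Gaussian smoothing (sigma 1 px by default; unspecified in the source
method and config-exposed) -> Canny -> removal of 8-connected edge
segments with <= 10 pixels. Canny thresholds are per view — 30/20
(left), 20/10 (right) — on the Sobel gradient-magnitude scale of the
8-bit intensities. Our Canny operator (scikit-image) smooths internally
at sigma 1; the gradient scale on which the published thresholds were
applied is not recorded, so these defaults are calibrated to the
synthetic renders and must be re-tuned per data source.

For a virtual projection the silhouette of the posed mesh is rasterised
through `P` (2D fill of all projected triangles — exact for silhouettes,
no ray casting needed), edge-enhanced with Canny at 300/200 on a 16-bit
intensity scale, filtered at > 100 px, then *graded-dilated*: the edge
mask is summed with its successive 3x3 dilations, producing a ramp
(3 on the contour, 2 at Chebyshev distance 1, 1 at distance 2 for the
default two iterations). A flat dilated mask would carry no intensity
gradient; the ramp is what gives the similarity a capture basin. The
implementation computes the ramp with a chessboard distance transform,
which is identical to iterated dilation but costs the same for any ramp
width. Edge-segment "length" is 8-connected pixel count.

## Similarity and objective

For bone *i* the similarity is the sum over the two views of the
uncentred cosine similarity between `F` and the graded virtual edge
image `V'`:

    S_i = (F_L . V'_L) / (|F_L| |V'_L|)  +  (F_R . V'_R) / (|F_R| |V'_R|)

The formula is implemented exactly as written — no mean subtraction —
even though such measures are often loosely called correlation
coefficients. A zero-norm factor (bone outside the view, or no edges)
makes that view's term 0 with a warning rather than an error, so
tracking can survive a bone transiently leaving the field.

Multi-bone scenes maximise

    I = sum_i ( S_i - sum_{j != i} mu D_ij ),      mu = 1000,

where `D_ij` is the penetration depth (mm) between bones i and j. The
inner sum is read literally, so each contacting pair is penalised in
both bones' terms; with mu = 1000 the factor-2 ambiguity cannot change
an optimum (any contact dwarfs the similarity range [0, 2]).

Penetration depth is approximated by bidirectional signed-distance
sampling: surface samples (vertices plus face centroids) of each mesh
are tested against the other mesh's signed distance field, and the
deepest penetration is taken (0 if disjoint, with an axis-aligned
bounding-box early-out). The public `penetration_depth` evaluates exact
point-to-triangle distances with inside/outside decided by ray-crossing
parity (numba kernels); the optimiser uses per-bone voxelised
signed-distance grids (0.4 mm pitch) for speed — accuracy ~ half a voxel
near the surface, which is ample for a penalty barrier.

## Optimisation

The objective is maximised by a quasi-Newton (BFGS) iteration whose
gradients are central finite differences. Because the objective is
built from quantised edge maps it is piecewise constant at sub-pixel
scales and rich in local optima, three devices make the search robust;
all three leave the *final* objective (full mu, dilation 2) untouched:

1. **Multiple finite-difference step sizes, chained coarse-to-fine.**
   Default sets (translation mm, rotation deg): (3, 3), (1, 2),
   (0.3, 1), (0.1, 0.4), (0.1, 0.15). Each run starts from the previous
   solution and the best final objective wins. Independent restarts
   from the shared initial guess (available via `chain_restarts=False`)
   fail in practice: at a 3 mm initial offset the fine-step runs see
   zero gradient. Rotation steps stay larger than translation steps
   because 0.3 deg moves contour pixels by less than the edge-map
   quantum (a degree of rotation displaces the contour far less than a
   millimetre of translation does).
2. **Stage-matched dilation.** During a coarse stage the graded ramp of
   `V'` is widened to the finite-difference step scale (same operator,
   more iterations), so the similarity has gradient at the initial
   perturbation distance. Fine stages use the standard ramp.
3. **Penalty continuation.** Coarse stages (and, in the sequential
   strategy, all but the final cycle) run with mu = 0. Otherwise bones
   optimised early are repelled from their true poses by penalty against
   neighbours still sitting at wrong, overlapping initial guesses.
4. **Similarity-guided restarts.** In crowded scenes a bone
   occasionally locks onto a neighbour's contour; its similarity then
   sits far below the scene's best. Bones ending with S below 0.7x the
   scene maximum are re-optimised from up to 6 seeded jitters of their
   initial guess (+/- 1.5 mm / 1.5 deg, widening every two attempts) on
   similarity alone, the best-S attempt wins, and the recovered bone is
   refined through the fine stages with the penalty back on.
5. **Rotation polish.** Because rotation moves contour pixels so much
   less than translation, a bone can settle with converged translation
   but ~1 deg of residual rotation and only slightly reduced S. Every
   bone is finally re-refined from two rotation-jittered (+/- 1.2 deg)
   copies of its solution through the fine stages; a candidate replaces
   the solution only if it improves both the similarity and the
   penalised per-bone objective.

The line search is Armijo backtracking with a steepest-ascent retry on
failure; a strong-Wolfe search would re-evaluate the 12-evaluation
finite-difference gradient at every trial point for no benefit on this
noisy objective. The inverse-Hessian seed is diag(steps^2), which also
fixes the mm/deg scaling.

Two strategies are offered: `joint` (all 6N parameters at once, the
default and the literal reading of the objective) and `sequential`
(cyclic per-bone optimisation with the others frozen), which is what the
multi-bone experiments use — it cuts the gradient cost from 12N to 12
evaluations per iteration and was equally accurate in our scenes. In
the sequential per-bone objective the moving bone's penalty term is
doubled, matching its appearance in both terms of the double sum.

Each objective evaluation renders only a cropped window around the
bone's projected bounding box (margin = 10 px + ramp width); since `V'`
vanishes outside the crop and the global norm of `F` is precomputed,
the cropped computation equals the full-image definition exactly.

## Frame-to-frame tracking

The first frame starts from user-supplied (manual) poses. For each
subsequent frame, 30x30 px templates centred on bony landmarks are
matched in both views by normalised cross-correlation over a +/- 40 px
search window with parabolic sub-pixel peak refinement; matches below
correlation 0.5 are dropped (both values are config-exposed; the source
method states neither). Matched landmarks are triangulated, each bone's
landmark set is fit by orthogonal Procrustes (Kabsch, proper rotation;
1-2 landmarks fall back to mean translation), and the resulting rigid
delta composed with the previous frame's solution seeds the optimiser.
Templates are re-extracted at the matched position after every frame. A
failed frame is recorded as unconverged and tracking continues from the
last good poses.

## Synthetic data

The generator stands in for the X-ray hardware, CT segmentation and
specimen:

* **Rig** — two point-source views 90 deg apart; 672x552 px panels at
  0.16 mm pitch; source-detector 600 mm, object at 400 mm
  (magnification 1.5, ~6.6 detector px per mm of object motion). The
  panel is a quarter-*size* cut-out of a clinical flat panel at its true
  pitch, not a downsampled one: marker triangulation at sub-0.1 mm needs
  the real pixel density, and the proxy bones are small enough to fit
  the reduced field of view.
* **Calibration phantom** — a planar L-shape (9 markers) plus a skew
  linear bar (5 markers): two objects whose union is non-coplanar.
* **Proxy bones** — superellipsoids (radii 9/6.5/5 mm at the default
  16 mm size) with a seeded sum of smooth radial bumps (amplitude 0.18)
  that breaks all reflection symmetries, so every pose parameter is
  observable from two silhouettes. Three landmarks at extremal vertices;
  four virtual "metal markers" at generic surface points provide truth
  poses via Procrustes, mirroring the physical accuracy protocol.
* **Scenes** — up to four bones on a 2x2 grid with a controlled
  inter-surface gap (default 0.5 mm; negative gaps create deliberate
  interpenetration for penalty tests).
* **Trajectories** — a Gaussian-smoothed random walk of the whole
  cluster (per-frame steps bounded, default <= 3 mm / 3 deg, emulating
  one stance phase at 15 frames) plus ~0.1 mm per-bone jitter.
* **Renders** — silhouettes superpose additively on an 8-bit background
  (overlaps brighten, so density edges appear where bones overlap, as in
  real radiographs), with Gaussian pixel noise (sigma 2) and optional
  low-frequency clutter. Additive rather than exponential attenuation
  is deliberate: only edges matter to the method, and additive
  superposition keeps contour contrast controllable.

What the synthetic data does *not* emulate: soft-tissue shadowing and
scatter (bone edges in vivo are far less distinct), genuinely anatomical
shapes and articular congruence, detector blur/veiling glare, and
template appearance change from out-of-plane rotation. Dry-bone
accuracy figures are therefore optimistic for in vivo use, and passing
the synthetic experiments demonstrates correctness of the pipeline, not
clinical accuracy.

## Accuracy experiments (scaled-down analogues)

* **Static**: 5 seeded placements of the 4-bone articulated scene, the
  whole cluster repositioned (+/- 5 mm, +/- 10 deg) per placement;
  initial guesses are truth perturbed by up to 3 mm / 3 deg per
  component. Errors are absolute per-component differences (angles
  wrapped to [0, 180] deg), pooled over bones, axes and placements.
* **Dynamic**: one 15-frame trajectory, template tracking enabled;
  first frame initialised like the static runs; warm-started frames use
  the shortened step schedule (1, 2) … (0.1, 0.15), still with two
  sequential cycles — a single penalised cycle lets small per-frame
  rotation residuals accumulate over the sequence.
* **Unarticulated**: the static protocol with single-bone scenes, two
  distinct bone shapes x 5 placements.
* **Calibration**: the phantom with 0.3 px Gaussian detection noise,
  DLT refit per view, all markers triangulated against truth.

Problem sizes (5 placements, 15 frames, 672x552 px, ~1.2k vertices per
bone) are the package's default desk-scale configuration; they complete
in roughly a quarter hour on one CPU.

Per-axis error metrics are component-wise absolute Euler differences,
matching how such experiments tabulate results; the geodesic rotation
angle is additionally available for diagnostics
(`evaluation.geodesic_rotation_error`).

## Known limitations

* The similarity's capture basin is set by the dilation ramp; initial
  poses beyond ~3-4 mm of truth need either template seeding or a wider
  coarse schedule.
* The penetration grid (0.4 mm voxels) can miss sub-voxel contacts;
  exact distances are used everywhere outside the inner loop.
* Sequential per-bone optimisation can in principle settle in a
  configuration a joint step would escape; in the test scenes the two
  agree to well under the reported error level.
* Canny thresholds are data-source specific. The defaults reproduce the
  published operating point on the synthetic renders' intensity scales;
  real acquisitions need recalibration.
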
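# bonetrack

Automatic model-based 2D/3D registration of individual foot bones from
biplanar X-ray fluoroscopy.

Measuring how the small tarsal bones (calcaneus, talus, navicular,
cuboid) move during gait is hard: skin markers slide over bone, bone
pins are invasive, and manually matching bone models to fluoroscopic
images frame by frame is slow and error-prone. `bonetrack` implements
an automatic pipeline for biplanar fluoroscopy: CT-derived triangle
meshes of each bone are posed in 3D so that their virtually projected
occluding contours line up with edge-enhanced X-ray images in both
views simultaneously, while a collision penalty keeps neighbouring
bones from interpenetrating. It is aimed at biomechanics researchers
running (or simulating) biplanar fluoroscopy studies of multi-bone
joint kinematics.

## Method

Each view is a point-source projection `P` (3x4, world mm -> pixels)
calibrated by the direct linear transformation (DLT) from marker
phantoms; 3D positions come from two-view triangulation. A fluoroscopic
frame is reduced to a binary edge image `F` (Gaussian smoothing, Canny,
short-segment removal); a bone model at a trial pose is rendered as a
silhouette whose Canny edges are graded-dilated into a ramp image `V'`.
The pose score of bone *i* sums the uncentred cosine similarity of `F`
and `V'` over the left and right views:

    S_i = (F_L . V'_L)/(|F_L||V'_L|) + (F_R . V'_R)/(|F_R||V'_R|)

and all bones are registered jointly by maximising

    I = sum_i ( S_i - sum_{j != i} mu D_ij ),     mu = 1000,

where `D_ij` is the penetration depth (mm) between bones i and j. The
maximisation is quasi-Newton with central finite differences at
multiple step sizes, run coarse-to-fine; frame-to-frame initial guesses
come from normalised cross-correlation template tracking of bony
landmarks (30x30 px windows), triangulated and fit by orthogonal
Procrustes. Poses are reported as translations (mm) plus intrinsic
y-x-z Euler angles (deg): phi plantar/dorsiflexion, theta
inversion/eversion, psi ab/adduction. See `docs/methods.md` for the
full model and numerical details.

A synthetic generator (`bonetrack.synthetic`) emulates the whole
acquisition — quasi-orthogonal rig, calibration phantom, lumpy
superellipsoid proxy bones with truth markers, smooth trajectories,
noisy attenuation-style renders — so every stage runs with no external
data.

## Worked example

Simulate a two-bone sequence, register it, and evaluate against the
generator's ground truth — all from the shell:

```
bonetrack demo --workdir demo_run --seed 1 --bones 2 --frames 5
```

which prints (seed 1):

```
calibration error 0.030 (0.012) mm
pooled translation 0.002 mm, rotation 0.099 deg -> demo_run
```

The first line is the mean (SD) 3D error of the synthetic calibration
phantom's markers after DLT calibration with 0.3 px detection noise —
i.e. how well the rig geometry was recovered. The second line pools the
absolute pose errors of both bones over all five tracked frames:
registered positions land within a few microns and well under a tenth
of a degree of the generator's ground truth on these clean synthetic
images. `demo_run/summary.md` holds the per-bone mean (SD) table and
`demo_run/errors.csv` the per-frame records.

The same stages are scriptable from Python:

```python
from bonetrack.evaluation import run_static_experiment, pooled_means
trials = run_static_experiment(seed=1, n_placements=5, n_bones=4)
print(pooled_means(trials))
```

Individual CLI stages: `bonetrack simulate`, `bonetrack calibrate`,
`bonetrack register`, `bonetrack evaluate`, `bonetrack validate`.

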
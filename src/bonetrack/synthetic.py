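"""Synthetic biplanar-fluoroscopy fixtures.

Generates everything the registration pipeline consumes, standing in for
the physical X-ray hardware, CT-derived meshes and cadaver specimen:

* a two-view point-source rig in a quasi-orthogonal arrangement,
* a two-object calibration phantom (planar L-shape + linear bar),
* lumpy superellipsoid proxy bones with landmarks and truth markers,
* articulated multi-bone scenes with a controlled inter-surface gap,
* smooth rigid trajectories, and
* attenuation-style biplanar renders with additive noise.

All randomness flows from the seed in :class:`SceneSpec`; identical specs
produce identical outputs.  The default desk-scale detector is 672x552
pixels at 0.16 mm pitch with 1.5x geometric magnification, so one
detector pixel spans about 0.11 mm at the object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bone_model import BoneMesh, Pose, matrix_to_pose, pose_to_matrix, transform_mesh
from .calibration import BiplanarRig, CalibrationObservation, ProjectionModel, project

__all__ = [
    "SceneSpec",
    "Scene",
    "make_rig",
    "make_calibration_phantom",
    "make_bone",
    "make_articulated_scene",
    "make_trajectory",
    "render_fluoro_image",
    "render_frames",
]

FLUORO_BACKGROUND = 20.0
FLUORO_BONE_GAIN = 70.0  # additive intensity per bone silhouette (8-bit scale)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic acquisition.

    Geometry defaults emulate a quasi-orthogonal biplanar rig at desk
    scale: 672x552 px flat panels (0.16 mm pitch), source-to-detector
    600 mm, object at 400 mm, views 90 deg apart.
    """

    # rig
    interview_angle_deg: float = 90.0
    source_detector_mm: float = 600.0
    source_object_mm: float = 400.0
    detector_px: tuple[int, int] = (672, 552)  # (width, height)
    pixel_pitch_mm: float = 0.16

    # bones
    n_bones: int = 4
    bone_size_mm: float = 16.0
    bone_subdivisions: int = 24  # uv-sphere resolution (verts ~ 2 n^2)
    lump_amplitude: float = 0.18
    gap_mm: float = 0.5

    # trajectory
    n_frames: int = 15
    max_step_translation_mm: float = 3.0
    max_step_rotation_deg: float = 3.0
    jitter_translation_mm: float = 0.1
    jitter_rotation_deg: float = 0.1

    # noise
    image_noise_sigma: float = 2.0
    clutter_amplitude: float = 0.0
    marker_noise_px: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not 30.0 < self.interview_angle_deg < 150.0:
            raise ValueError("inter-view angle must lie in (30, 150) deg")
        if not 1 <= self.n_bones <= 4:
            raise ValueError("n_bones must be 1..4")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Scene:
    """Reference bones (centroid at origin) plus their placement poses."""

    spec: SceneSpec
    rig: BiplanarRig
    bones: list[BoneMesh]
    placement: list[Pose]


def _rng(spec_seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed), int(tag)]))


# ---------------------------------------------------------------------------
# rig
# ---------------------------------------------------------------------------

def _view_model(spec: SceneSpec, azimuth_deg: float, view_id: str) -> ProjectionModel:
    a = np.radians(azimuth_deg)
    d = np.array([np.sin(a), np.cos(a), 0.0])  # source -> detector axis
    C = -spec.source_object_mm * d
    z_cam = d
    y_cam = np.array([0.0, 0.0, -1.0])  # image v grows downward = world -z
    x_cam = np.cross(y_cam, z_cam)
    R = np.vstack([x_cam, y_cam, z_cam])
    f = spec.source_detector_mm / spec.pixel_pitch_mm
    w, h = spec.detector_px
    K = np.array([[f, 0.0, (w - 1) / 2.0], [0.0, f, (h - 1) / 2.0], [0.0, 0.0, 1.0]])
    P = K @ np.hstack([R, (-R @ C)[:, None]])
    return ProjectionModel(
        P=P / np.linalg.norm(P), image_width=w, image_height=h, view_id=view_id
    )


def make_rig(spec: SceneSpec) -> BiplanarRig:
    """Two perspective views separated by the configured inter-view angle."""
    half = spec.interview_angle_deg / 2.0
    return BiplanarRig(
        left=_view_model(spec, -half, "L"),
        right=_view_model(spec, +half, "R"),
        world_frame_note=(
            "origin at the centre of the measurement volume; z vertical; "
            f"views at +/-{half:g} deg azimuth"
        ),
    )


# ---------------------------------------------------------------------------
# calibration phantom
# ---------------------------------------------------------------------------

def make_calibration_phantom(
    spec: SceneSpec, noise_px: float | None = None
) -> tuple[np.ndarray, dict[str, CalibrationObservation]]:
    """Two-object phantom: planar L-shape plus a skew linear bar.

    Returns the true 3D marker coordinates and one
    :class:`CalibrationObservation` per view, with optional Gaussian
    marker-detection noise (px).
    """
    if noise_px is None:
        noise_px = spec.marker_noise_px
    s = 22.0  # phantom arm half-length, mm
    arm_x = [(-s + i * (2 * s / 4), -14.0, -12.0) for i in range(5)]
    arm_y = [(-s, -14.0 + (i + 1) * 7.0, -12.0) for i in range(4)]
    bar = [
        tuple(np.array([-12.0, -12.0, -16.0]) + t * np.array([24.0, 24.0, 32.0]))
        for t in np.linspace(0.0, 1.0, 5)
    ]
    pts = np.array(arm_x + arm_y + bar, dtype=float)
    rig = make_rig(spec)
    rng = _rng(spec.seed, 101)
    obs = {}
    for vid, model in rig.views.items():
        uv = project(model, pts)
        uv = uv + rng.normal(0.0, noise_px, uv.shape) if noise_px > 0 else uv
        obs[vid] = CalibrationObservation(
            points3d=pts,
            points2d=uv,
            view_id=vid,
            image_width=model.image_width,
            image_height=model.image_height,
        )
    return pts, obs


# ---------------------------------------------------------------------------
# proxy bones
# ---------------------------------------------------------------------------

def _uv_sphere(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Watertight unit uv-sphere with n latitude bands and 2n longitudes."""
    import trimesh

    m = trimesh.creation.uv_sphere(radius=1.0, count=(n, 2 * n))
    m.merge_vertices()
    return np.asarray(m.vertices, float), np.asarray(m.faces, np.int64)


def make_bone(spec: SceneSpec, bone_index: int = 0) -> BoneMesh:
    """Lumpy superellipsoid proxy bone with landmarks and truth markers.

    The base shape is a superellipsoid with three distinct radii; a seeded
    sum of smooth radial bumps breaks its reflection symmetries so that
    all six pose parameters are observable from the two silhouettes.
    Three landmarks sit at extremal surface vertices and four virtual
    'metal markers' (for truth poses) at generic surface points.
    """
    rng = _rng(spec.seed, 1000 + bone_index)
    verts, faces = _uv_sphere(spec.bone_subdivisions)
    n = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    scale = spec.bone_size_mm / 16.0
    a, b, c = 9.0 * scale, 6.5 * scale, 5.0 * scale
    p = 2.6  # superellipsoid exponent (slightly boxy)
    r = (
        np.abs(n[:, 0] / a) ** p + np.abs(n[:, 1] / b) ** p + np.abs(n[:, 2] / c) ** p
    ) ** (-1.0 / p)
    # smooth asymmetric bumps
    k = 6
    centers = rng.normal(size=(k, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    weights = rng.uniform(-1.0, 1.0, k) * spec.lump_amplitude
    widths = rng.uniform(0.08, 0.2, k)
    bump = np.zeros(len(n))
    for ck, wk, sk in zip(centers, weights, widths):
        bump += wk * np.exp(-(1.0 - n @ ck) / sk)
    r = r * (1.0 + bump)
    verts = n * r[:, None]

    mesh = BoneMesh(name=f"bone{bone_index}", vertices=verts, faces=faces)
    mesh.vertices = mesh.vertices - mesh.centroid  # anatomical origin = centroid

    v = mesh.vertices
    mesh.landmarks = {
        "max_x": v[np.argmax(v[:, 0])].copy(),
        "max_y": v[np.argmax(v[:, 1])].copy(),
        "max_z": v[np.argmax(v[:, 2])].copy(),
    }
    marker_dirs = np.array(
        [[1.0, 0.2, 0.1], [-0.8, 0.6, 0.0], [0.0, -0.7, 0.7], [0.3, 0.3, -0.9]]
    )
    mesh.markers = {
        f"m{j}": v[np.argmax(v @ d / np.linalg.norm(d))].copy()
        for j, d in enumerate(marker_dirs)
    }
    return mesh


# ---------------------------------------------------------------------------
# articulated scenes
# ---------------------------------------------------------------------------

def make_articulated_scene(spec: SceneSpec) -> Scene:
    """Cluster of 1-4 proxy bones with a controlled inter-surface gap.

    Bones are laid out on a 2x2 grid in the x-z plane; the spacing of
    each facing pair is set from the bones' axis-aligned extents so that
    the nominal surface gap equals ``spec.gap_mm`` (negative values
    create deliberate interpenetration for penalty tests).
    """
    rig = make_rig(spec)
    bones = [make_bone(spec, i) for i in range(spec.n_bones)]
    gap = spec.gap_mm
    centers = [np.zeros(3) for _ in bones]
    if spec.n_bones >= 2:  # bone1 to the +x of bone0
        dx = bones[0].vertices[:, 0].max() - bones[1].vertices[:, 0].min() + gap
        centers[1] = np.array([dx, 0.0, 0.0])
    if spec.n_bones >= 3:  # bone2 above bone0
        dz = bones[0].vertices[:, 2].max() - bones[2].vertices[:, 2].min() + gap
        centers[2] = np.array([0.0, 0.0, dz])
    if spec.n_bones == 4:  # bone3 above bone1
        dz = bones[1].vertices[:, 2].max() - bones[3].vertices[:, 2].min() + gap
        centers[3] = centers[1] + np.array([0.0, 0.0, dz])
    mid = np.mean(centers, axis=0)
    placement = [Pose(*(c - mid)) for c in centers]
    return Scene(spec=spec, rig=rig, bones=bones, placement=placement)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def make_trajectory(spec: SceneSpec, scene: Scene) -> list[list[Pose]]:
    """Smooth rigid motion: frame-indexed list of per-bone poses.

    A cubic-smoothed random walk moves the whole cluster (per-frame steps
    bounded by the spec's translation/rotation limits); each bone adds a
    small independent jitter, so inter-bone gaps are preserved.  Frame 0
    equals the scene placement.
    """
    from scipy import ndimage as ndi
    from scipy.spatial.transform import Rotation

    rng = _rng(spec.seed, 2000)
    F = spec.n_frames
    raw = rng.uniform(-1.0, 1.0, size=(F, 6))
    sm = ndi.gaussian_filter1d(raw, sigma=1.5, axis=0, mode="nearest")
    dt = sm[:, :3]
    dr = sm[:, 3:]
    tn = np.linalg.norm(dt, axis=1).max()
    rn = np.linalg.norm(dr, axis=1).max()
    dt = dt * (0.85 * spec.max_step_translation_mm / max(tn, 1e-12))
    dr = dr * (0.85 * spec.max_step_rotation_deg / max(rn, 1e-12))

    frames: list[list[Pose]] = []
    C = np.eye(4)
    for f in range(F):
        if f > 0:
            D = np.eye(4)
            D[:3, :3] = Rotation.from_rotvec(np.radians(dr[f])).as_matrix()
            D[:3, 3] = dt[f]
            C = D @ C
        poses = []
        for b, place in enumerate(scene.placement):
            T = C @ pose_to_matrix(place)
            if f > 0 and (spec.jitter_translation_mm > 0 or spec.jitter_rotation_deg > 0):
                jr = _rng(spec.seed, 3000 + 100 * f + b)
                J = np.eye(4)
                J[:3, :3] = Rotation.from_rotvec(
                    np.radians(jr.normal(0, spec.jitter_rotation_deg / 3.0, 3))
                ).as_matrix()
                J[:3, 3] = jr.normal(0, spec.jitter_translation_mm / 3.0, 3)
                T = J @ T
            poses.append(matrix_to_pose(T))
        frames.append(poses)
    return frames


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_fluoro_image(
    model: ProjectionModel,
    bones: list[BoneMesh],
    poses: list[Pose],
    noise_sigma: float = 2.0,
    clutter_amplitude: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """8-bit attenuation-style render: silhouettes superpose additively.

    Overlapping bones darken (here: brighten) additively, emulating
    radiographic superposition, so density edges appear where silhouettes
    overlap just as in real biplanar radiographs.
    """
    from .imaging import project_mesh_silhouette

    img = np.full((model.image_height, model.image_width), FLUORO_BACKGROUND)
    for mesh, pose in zip(bones, poses):
        img += FLUORO_BONE_GAIN * project_mesh_silhouette(model, mesh, pose)
    if rng is None:
        rng = np.random.default_rng(0)
    if clutter_amplitude > 0:
        from scipy import ndimage as ndi

        bg = rng.normal(0.0, 1.0, img.shape)
        bg = ndi.gaussian_filter(bg, 25.0)
        bg *= clutter_amplitude / max(np.abs(bg).max(), 1e-12)
        img += bg
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_frames(
    scene: Scene,
    trajectory: list[list[Pose]],
    outdir: str | Path | None = None,
) -> dict:
    """Render the biplanar image sequence plus all ground-truth tables.

    Returns a dict with ``images`` (frame-indexed {'L','R'} uint8 arrays),
    ``truth_poses`` (DataFrame: frame, bone, x..psi), ``markers``
    (DataFrame of per-frame marker pixel positions in both views, with
    detection noise), and ``landmarks0`` (frame-0 landmark pixels for
    template initialisation).  If ``outdir`` is given, PNGs and CSVs are
    written there.
    """
    spec = scene.spec
    rig = scene.rig
    images = []
    truth_rows = []
    marker_rows = []
    lm_rows = []
    mrng = _rng(spec.seed, 4000)
    for f, poses in enumerate(trajectory):
        frame_imgs = {}
        for vid, model in rig.views.items():
            irng = _rng(spec.seed, 5000 + 10 * f + (0 if vid == "L" else 1))
            frame_imgs[vid] = render_fluoro_image(
                model,
                scene.bones,
                poses,
                noise_sigma=spec.image_noise_sigma,
                clutter_amplitude=spec.clutter_amplitude,
                rng=irng,
            )
        images.append(frame_imgs)
        for b, (mesh, pose) in enumerate(zip(scene.bones, poses)):
            truth_rows.append(
                dict(frame=f, bone=mesh.name, **dataclasses.asdict(pose))
            )
            posed = transform_mesh(mesh, pose)
            for mname, mpt in posed.markers.items():
                row = dict(frame=f, bone=mesh.name, marker=mname)
                row.update(X=mpt[0], Y=mpt[1], Z=mpt[2])
                for vid, model in rig.views.items():
                    uv = project(model, mpt)
                    if spec.marker_noise_px > 0:
                        uv = uv + mrng.normal(0.0, spec.marker_noise_px, 2)
                    row[f"u_{vid}"], row[f"v_{vid}"] = uv
                marker_rows.append(row)
            if f == 0:
                for lname, lpt in posed.landmarks.items():
                    row = dict(frame=0, bone=mesh.name, landmark=lname)
                    for vid, model in rig.views.items():
                        uv = project(model, lpt)
                        row[f"u_{vid}"], row[f"v_{vid}"] = uv
                    lm_rows.append(row)
    out = {
        "images": images,
        "truth_poses": pd.DataFrame(truth_rows),
        "markers": pd.DataFrame(marker_rows),
        "landmarks0": pd.DataFrame(lm_rows),
        "spec_hash": spec.content_hash(),
    }
    if outdir is not None:
        _write_outputs(scene, out, Path(outdir))
    return out


def _write_outputs(scene: Scene, out: dict, outdir: Path) -> None:
    import imageio.v3 as iio

    from .bone_model import write_mesh
    from .calibration import save_rig

    for vid in ("L", "R"):
        d = outdir / f"frames_{vid}"
        d.mkdir(parents=True, exist_ok=True)
        for f, frame in enumerate(out["images"]):
            iio.imwrite(d / f"frame_{f:04d}.png", frame[vid])
    save_rig(scene.rig, outdir / "rig.json")
    bdir = outdir / "bones"
    bdir.mkdir(exist_ok=True)
    for mesh in scene.bones:
        write_mesh(mesh, bdir / f"{mesh.name}.ply")
    lm_rows = []
    for mesh in scene.bones:
        for name, p in mesh.landmarks.items():
            lm_rows.append(dict(bone=mesh.name, landmark_name=name, X=p[0], Y=p[1], Z=p[2]))
        for name, p in mesh.markers.items():
            lm_rows.append(dict(bone=mesh.name, landmark_name=name, X=p[0], Y=p[1], Z=p[2]))
    pd.DataFrame(lm_rows).to_csv(outdir / "landmarks.csv", index=False)
    out["truth_poses"].to_csv(outdir / "truth_poses.csv", index=False)
    out["markers"].to_csv(outdir / "markers.csv", index=False)
    out["landmarks0"].to_csv(outdir / "landmarks0.csv", index=False)
    meta = dataclasses.asdict(scene.spec)
    meta["spec_hash"] = out["spec_hash"]
    with open(outdir / "scene_spec.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
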
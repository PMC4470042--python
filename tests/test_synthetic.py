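"""The synthetic biplanar generator: rigs, phantoms, bones, scenes, renders."""

import dataclasses

import numpy as np
import pytest

from bonetrack.bone_model import Pose, transform_mesh
from bonetrack.calibration import (
    BiplanarRig,
    calibration_error,
    estimate_dlt,
    project,
    triangulate,
)
from bonetrack.imaging import EdgeParams, make_F
from bonetrack.registration import EdgeMatcher, penetration_depth
from bonetrack.synthetic import (
    SceneSpec,
    make_articulated_scene,
    make_bone,
    make_calibration_phantom,
    make_rig,
    make_trajectory,
    render_fluoro_image,
    render_frames,
)


# ---------------------------------------------------------------------------
# rig
# ---------------------------------------------------------------------------

def test_rig_orthogonal_axes(spec, rig):
    assert rig.interview_angle_deg == pytest.approx(90.0, abs=1e-9)
    assert abs(np.dot(rig.left.principal_axis, rig.right.principal_axis)) < 1e-9


def test_rig_round_trip(rig, rng):
    for p in rng.uniform(-15, 15, (10, 3)):
        X, _ = triangulate(rig, project(rig.left, p), project(rig.right, p))
        assert np.linalg.norm(X - p) < 1e-6


def test_rig_dlt_refit_self_consistent(spec, rig, rng):
    """DLT refit from 12 virtual markers reproduces the projections."""
    from bonetrack.calibration import CalibrationObservation

    pts = rng.uniform(-18, 18, (12, 3))
    for model in (rig.left, rig.right):
        uv = project(model, pts)
        refit = estimate_dlt(CalibrationObservation(points3d=pts, points2d=uv))
        probe = rng.uniform(-15, 15, (30, 3))
        assert np.abs(project(refit, probe) - project(model, probe)).max() < 1e-6


def test_rig_angle_bounds_enforced():
    with pytest.raises(ValueError):
        SceneSpec(interview_angle_deg=20.0)


# ---------------------------------------------------------------------------
# calibration phantom
# ---------------------------------------------------------------------------

def test_phantom_noise_free_calibrates_exactly(spec, rig):
    pts, obs = make_calibration_phantom(spec, noise_px=0.0)
    fit = BiplanarRig(left=estimate_dlt(obs["L"]), right=estimate_dlt(obs["R"]))
    mean, _ = calibration_error(fit, pts, obs["L"].points2d, obs["R"].points2d)
    assert mean < 1e-6


def test_phantom_noise_gives_positive_error(spec, rig):
    pts, obs = make_calibration_phantom(spec, noise_px=0.3)
    mean, _ = calibration_error(rig, pts, obs["L"].points2d, obs["R"].points2d)
    assert mean > 0


def test_phantom_too_few_markers_rejected(spec):
    from bonetrack.calibration import CalibrationObservation

    pts, obs = make_calibration_phantom(spec, noise_px=0.0)
    small = CalibrationObservation(
        points3d=obs["L"].points3d[:5], points2d=obs["L"].points2d[:5]
    )
    with pytest.raises(ValueError, match="insufficient"):
        estimate_dlt(small)


# ---------------------------------------------------------------------------
# bones
# ---------------------------------------------------------------------------

def test_bone_watertight_and_centred(spec):
    bone = make_bone(spec, 0)
    assert bone.boundary_edge_fraction() == 0.0
    assert np.allclose(bone.centroid, 0.0, atol=1e-9)
    assert len(bone.landmarks) == 3 and len(bone.markers) == 4


def test_bones_distinct_across_seeds():
    a = make_bone(SceneSpec(seed=1), 0)
    b = make_bone(SceneSpec(seed=2), 0)
    d = np.linalg.norm(a.vertices - b.vertices, axis=1).max()
    assert d > 0.1


def test_bone_markers_not_coplanar(spec):
    m = np.array(list(make_bone(spec, 0).markers.values()))
    vol = abs(np.linalg.det(m[1:] - m[0]))
    assert vol > 1.0


def test_bone_silhouette_area_varies_with_rotation(small_spec):
    """All-axis pose observability: the silhouette changes under rotation."""
    from bonetrack.imaging import project_mesh_silhouette

    rig = make_rig(small_spec)
    bone = make_bone(small_spec, 0)
    areas = [
        project_mesh_silhouette(rig.left, bone, Pose(psi=a)).sum()
        for a in np.arange(0, 360, 30)
    ]
    assert (max(areas) - min(areas)) / max(areas) > 0.02


# ---------------------------------------------------------------------------
# scenes and trajectories
# ---------------------------------------------------------------------------

def test_scene_positive_gap_no_penetration(small_spec):
    spec = dataclasses.replace(small_spec, n_bones=4, gap_mm=0.5)
    scene = make_articulated_scene(spec)
    posed = [transform_mesh(b, p) for b, p in zip(scene.bones, scene.placement)]
    for i in range(4):
        for j in range(i + 1, 4):
            assert penetration_depth(posed[i], posed[j]) == 0.0


def test_scene_negative_gap_penetrates(small_spec):
    spec = dataclasses.replace(small_spec, n_bones=2, gap_mm=-0.3)
    scene = make_articulated_scene(spec)
    posed = [transform_mesh(b, p) for b, p in zip(scene.bones, scene.placement)]
    d = penetration_depth(posed[0], posed[1])
    # sphere-like overlap: depth of the order of the configured overlap
    assert 0.05 < d < 0.45


def test_bone_count_configurable(small_spec):
    for n in (1, 2, 3, 4):
        scene = make_articulated_scene(dataclasses.replace(small_spec, n_bones=n))
        assert len(scene.bones) == n


def test_trajectory_zero_motion_constant(small_spec):
    spec = dataclasses.replace(
        small_spec,
        n_frames=4,
        max_step_translation_mm=0.0,
        max_step_rotation_deg=0.0,
        jitter_translation_mm=0.0,
        jitter_rotation_deg=0.0,
    )
    scene = make_articulated_scene(spec)
    traj = make_trajectory(spec, scene)
    for frame in traj[1:]:
        for p, q in zip(frame, traj[0]):
            assert np.allclose(p.as_vector(), q.as_vector(), atol=1e-9)


def test_trajectory_first_frame_is_placement(small_spec):
    spec = dataclasses.replace(small_spec, n_frames=6)
    scene = make_articulated_scene(spec)
    traj = make_trajectory(spec, scene)
    for p, q in zip(traj[0], scene.placement):
        assert np.allclose(p.as_vector(), q.as_vector(), atol=1e-12)


def test_trajectory_steps_within_bounds(small_spec):
    from bonetrack.bone_model import pose_to_matrix

    spec = dataclasses.replace(small_spec, n_frames=8)
    scene = make_articulated_scene(spec)
    traj = make_trajectory(spec, scene)
    for f in range(1, 8):
        for b in range(len(scene.bones)):
            T0 = pose_to_matrix(traj[f - 1][b])
            T1 = pose_to_matrix(traj[f][b])
            D = T1 @ np.linalg.inv(T0)
            t = np.linalg.norm(D[:3, 3])
            ang = np.degrees(
                np.arccos(np.clip((np.trace(D[:3, :3]) - 1) / 2, -1, 1))
            )
            # cluster step bound plus the small per-bone jitter
            assert t < spec.max_step_translation_mm + 3 * spec.jitter_translation_mm + 1.0
            assert ang < spec.max_step_rotation_deg + 3 * spec.jitter_rotation_deg + 1.0


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_render_deterministic_per_seed(small_spec):
    spec = dataclasses.replace(small_spec, n_frames=2, n_bones=2)
    scene = make_articulated_scene(spec)
    traj = make_trajectory(spec, scene)
    a = render_frames(scene, traj)
    b = render_frames(scene, traj)
    for fa, fb in zip(a["images"], b["images"]):
        assert np.array_equal(fa["L"], fb["L"]) and np.array_equal(fa["R"], fb["R"])


def test_render_overlap_is_additive(small_spec, rig):
    bone = make_bone(small_spec, 0)
    rig_s = make_rig(small_spec)
    apart = render_fluoro_image(
        rig_s.left, [bone, bone], [Pose(-10, 0, 0), Pose(10, 0, 0)], noise_sigma=0
    )
    onto = render_fluoro_image(
        rig_s.left, [bone, bone], [Pose(), Pose()], noise_sigma=0
    )
    assert onto.max() > apart.max()  # superposition brightens the overlap


def test_render_single_bone_closed_contour(small_spec):
    spec = dataclasses.replace(small_spec, n_bones=1, image_noise_sigma=0.0)
    scene = make_articulated_scene(spec)
    img = render_fluoro_image(
        scene.rig.views["L"], scene.bones, scene.placement, noise_sigma=0.0
    )
    from scipy import ndimage as ndi

    F = make_F(img, EdgeParams(), "L").pixels
    filled = ndi.binary_fill_holes(F)
    assert filled.sum() > 5 * F.sum()  # the contour encloses a region


def test_truth_tables_written(tmp_path, small_spec):
    spec = dataclasses.replace(small_spec, n_frames=2, n_bones=2)
    scene = make_articulated_scene(spec)
    traj = make_trajectory(spec, scene)
    out = render_frames(scene, traj, outdir=tmp_path)
    assert (tmp_path / "rig.json").exists()
    assert len(list((tmp_path / "frames_L").glob("*.png"))) == 2
    assert len(out["truth_poses"]) == 4
    assert set(out["markers"]["marker"]) == {"m0", "m1", "m2", "m3"}


def test_marker_truth_recovers_generator_poses(small_spec):
    """Markers triangulated from their projections reproduce the truth pose."""
    from bonetrack.evaluation import marker_truth_pose, pose_errors

    spec = dataclasses.replace(small_spec, n_frames=1, n_bones=2, marker_noise_px=0.0)
    scene = make_articulated_scene(spec)
    traj = make_trajectory(spec, scene)
    data = render_frames(scene, traj)
    mk = data["markers"]
    for b, mesh in enumerate(scene.bones):
        sub = mk[mk["bone"] == mesh.name]
        obs3d = []
        for _, row in sub.iterrows():
            X, _ = triangulate(
                scene.rig, (row["u_L"], row["v_L"]), (row["u_R"], row["v_R"])
            )
            obs3d.append(X)
        ref = np.array([mesh.markers[m] for m in sub["marker"]])
        pose, rms = marker_truth_pose(ref, np.array(obs3d))
        assert rms < 0.05
        errs = pose_errors(pose, traj[0][b])
        assert max(errs.values()) < 0.05


def test_objective_peaks_at_truth_per_parameter(small_spec):
    """Identifiability: each pose parameter's 1D sweep peaks at the truth."""
    spec = dataclasses.replace(small_spec, n_bones=1, image_noise_sigma=0.0)
    scene = make_articulated_scene(spec)
    imgs = {
        vid: render_fluoro_image(model, scene.bones, scene.placement, noise_sigma=0.0)
        for vid, model in scene.rig.views.items()
    }
    m = EdgeMatcher(scene.rig, scene.bones, imgs)
    truth = scene.placement[0].as_vector()
    for k in range(6):
        step = 0.1 if k < 3 else 0.4
        sweep = np.arange(-3, 3.01) * step
        vals = []
        for d in sweep:
            v = truth.copy()
            v[k] += d
            vals.append(m.bone_similarity(0, Pose.from_vector(v)).total)
        assert abs(sweep[int(np.argmax(vals))]) <= step + 1e-12
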
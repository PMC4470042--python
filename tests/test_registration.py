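"""Similarity, penetration depth and pose optimisation."""

import numpy as np
import pytest
import trimesh

from bonetrack.bone_model import BoneMesh, Pose
from bonetrack.imaging import EdgeImage
from bonetrack.registration import (
    EdgeMatcher,
    OptimizerConfig,
    PenetrationReport,
    optimize_frame,
    penetration_depth,
    similarity,
    track_sequence,
)
from bonetrack.synthetic import (
    SceneSpec,
    make_articulated_scene,
    render_fluoro_image,
)


def _edge(arr, kind="fluoro"):
    return EdgeImage(np.asarray(arr), kind=kind)


def _bone_from_trimesh(tm, name):
    return BoneMesh(name=name, vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


@pytest.fixture(scope="module")
def small_scene():
    spec = SceneSpec(
        seed=5,
        n_bones=1,
        detector_px=(336, 276),
        pixel_pitch_mm=0.16,
        bone_size_mm=12.0,
        bone_subdivisions=18,
    )
    scene = make_articulated_scene(spec)
    imgs = {
        vid: render_fluoro_image(
            model,
            scene.bones,
            scene.placement,
            noise_sigma=2.0,
            rng=np.random.default_rng([5, ord(vid)]),
        )
        for vid, model in scene.rig.views.items()
    }
    return scene, imgs


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def test_similarity_identical_images_is_two():
    f = np.zeros((4, 4), np.uint8)
    f[1, 1:3] = 1
    s = similarity(_edge(f), _edge(f), _edge(f, "virtual_dilated"), _edge(f, "virtual_dilated"))
    assert s.total == pytest.approx(2.0)


def test_similarity_disjoint_supports_zero():
    a = np.zeros((4, 4), np.uint8)
    b = np.zeros((4, 4), np.uint8)
    a[0, 0] = 1
    b[3, 3] = 1
    s = similarity(_edge(a), _edge(a), _edge(b, "virtual_dilated"), _edge(b, "virtual_dilated"))
    assert s.total == 0.0


def test_similarity_hand_computed_example():
    # left: F = [1,0,1,0], V' = [3,2,1,0] -> 4 / (sqrt(2) sqrt(14))
    F_L = np.array([[1, 0], [1, 0]], np.uint8)
    Vp_L = np.array([[3, 2], [1, 0]], np.uint16)
    F_R = np.array([[1]], np.uint8)
    Vp_R = np.array([[1]], np.uint16)
    s = similarity(
        _edge(F_L), _edge(F_R), _edge(Vp_L, "virtual_dilated"), _edge(Vp_R, "virtual_dilated")
    )
    assert s.left == pytest.approx(4 / (np.sqrt(2) * np.sqrt(14)))
    assert s.total == pytest.approx(1.0 + 4 / (np.sqrt(2) * np.sqrt(14)))


def test_similarity_zero_norm_term_is_zero_with_warning():
    empty = np.zeros((3, 3), np.uint8)
    full = np.ones((3, 3), np.uint8)
    with pytest.warns(UserWarning, match="zero-norm"):
        s = similarity(
            _edge(empty), _edge(full), _edge(full, "virtual_dilated"), _edge(full, "virtual_dilated")
        )
    assert s.left == 0.0 and s.right == pytest.approx(1.0)


def test_similarity_scale_invariant(rng):
    f = (rng.uniform(size=(6, 6)) < 0.4).astype(np.uint8)
    v = rng.integers(0, 4, (6, 6)).astype(np.uint16)
    s1 = similarity(_edge(f), _edge(f), _edge(v, "virtual_dilated"), _edge(v, "virtual_dilated"))
    s2 = similarity(
        _edge(f), _edge(f), _edge(v * 3, "virtual_dilated"), _edge(v * 3, "virtual_dilated")
    )
    assert s1.total == pytest.approx(s2.total, abs=1e-12)


def test_similarity_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        similarity(
            _edge(np.ones((2, 2), np.uint8)),
            _edge(np.ones((2, 2), np.uint8)),
            _edge(np.ones((3, 3), np.uint16), "virtual_dilated"),
            _edge(np.ones((2, 2), np.uint16), "virtual_dilated"),
        )


# ---------------------------------------------------------------------------
# penetration depth
# ---------------------------------------------------------------------------

def test_penetration_disjoint_spheres_zero():
    a = _bone_from_trimesh(trimesh.creation.icosphere(2, 1.0), "a")
    b = _bone_from_trimesh(trimesh.creation.icosphere(2, 1.0), "b")
    b.vertices = b.vertices + [3.0, 0, 0]
    assert penetration_depth(a, b) == 0.0


def test_penetration_overlapping_spheres_analytic():
    # r1 + r2 - d = 1 + 1 - 1.5 = 0.5
    a = _bone_from_trimesh(trimesh.creation.icosphere(3, 1.0), "a")
    b = _bone_from_trimesh(trimesh.creation.icosphere(3, 1.0), "b")
    b.vertices = b.vertices + [1.5, 0, 0]
    assert penetration_depth(a, b) == pytest.approx(0.5, abs=0.05)


def test_penetration_overlapping_cubes():
    a = _bone_from_trimesh(trimesh.creation.box((1.0, 1.0, 1.0)), "a")
    b = _bone_from_trimesh(trimesh.creation.box((1.0, 1.0, 1.0)), "b")
    b.vertices = b.vertices + [0.8, 0.0, 0.0]  # 0.2 overlap along x only
    assert penetration_depth(a, b) == pytest.approx(0.2, abs=0.02)


def test_penetration_report_validates():
    with pytest.raises(ValueError):
        PenetrationReport(D=np.array([[0.0, 1.0], [2.0, 0.0]]))


# ---------------------------------------------------------------------------
# objective structure
# ---------------------------------------------------------------------------

def test_single_bone_objective_equals_similarity(small_scene):
    scene, imgs = small_scene
    m = EdgeMatcher(scene.rig, scene.bones, imgs)
    pose = scene.placement[0]
    obj = m.objective([pose])
    assert obj.I == pytest.approx(m.bone_similarity(0, pose).total)
    assert obj.penalty == [0.0]


def test_objective_penalty_arithmetic(small_scene):
    """I = sum_i S_i - mu * sum_ij D_ij with symmetric pair counting."""
    spec = SceneSpec(
        seed=5,
        n_bones=2,
        gap_mm=-0.4,  # deliberate interpenetration
        detector_px=(336, 276),
        pixel_pitch_mm=0.16,
        bone_size_mm=12.0,
        bone_subdivisions=18,
    )
    scene = make_articulated_scene(spec)
    imgs = {
        vid: render_fluoro_image(model, scene.bones, scene.placement, noise_sigma=0.0)
        for vid, model in scene.rig.views.items()
    }
    m = EdgeMatcher(scene.rig, scene.bones, imgs)
    obj = m.objective(scene.placement)
    D = obj.penetration.D
    assert D[0, 1] > 0.05  # bones really do interpenetrate
    S = [m.bone_similarity(i, p).total for i, p in enumerate(scene.placement)]
    assert obj.I == pytest.approx(sum(S) - m.mu * D.sum(), rel=1e-9)


def test_objective_mu_zero_ignores_contact(small_scene):
    spec = SceneSpec(
        seed=5, n_bones=2, gap_mm=-0.4, detector_px=(336, 276),
        pixel_pitch_mm=0.16, bone_size_mm=12.0, bone_subdivisions=18,
    )
    scene = make_articulated_scene(spec)
    imgs = {
        vid: render_fluoro_image(model, scene.bones, scene.placement, noise_sigma=0.0)
        for vid, model in scene.rig.views.items()
    }
    m = EdgeMatcher(scene.rig, scene.bones, imgs, mu=0.0)
    obj = m.objective(scene.placement)
    assert obj.I == pytest.approx(sum(obj.S))


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

def test_truth_initialisation_is_fixed_point(small_scene):
    scene, imgs = small_scene
    m = EdgeMatcher(scene.rig, scene.bones, imgs)
    truth = scene.placement[0]
    fr = optimize_frame(m, [truth], OptimizerConfig())
    err = np.abs(fr.poses[0].as_vector() - truth.as_vector())
    assert err[:3].max() < 0.05 and err[3:].max() < 0.05


def test_perturbed_single_bone_recovery(small_scene):
    scene, imgs = small_scene
    m = EdgeMatcher(scene.rig, scene.bones, imgs)
    truth = scene.placement[0]
    rng = np.random.default_rng(21)
    init = Pose.from_vector(
        truth.as_vector() + np.concatenate([rng.uniform(-2, 2, 3), rng.uniform(-2, 2, 3)])
    )
    fr = optimize_frame(m, [init], OptimizerConfig())
    err = np.abs(fr.poses[0].as_vector() - truth.as_vector())
    assert err[:3].max() < 0.5 and err[3:].max() < 0.5
    assert fr.converged


def test_grid_search_oracle_agreement(small_scene):
    """On an (x, phi) slice the optimiser agrees with exhaustive search."""
    scene, imgs = small_scene
    m = EdgeMatcher(scene.rig, scene.bones, imgs)
    truth = scene.placement[0].as_vector()

    def slice_obj(dx, dphi):
        v = truth.copy()
        v[0] += dx
        v[3] += dphi
        return m.bone_similarity(0, Pose.from_vector(v)).total

    xs = np.arange(-1.0, 1.01, 0.25)
    ps = np.arange(-2.0, 2.01, 0.5)
    grid = np.array([[slice_obj(dx, dp) for dp in ps] for dx in xs])
    gi, gj = np.unravel_index(np.argmax(grid), grid.shape)
    init = truth.copy()
    init[0] += 0.75
    init[3] += 1.5
    fr = optimize_frame(m, [Pose.from_vector(init)], OptimizerConfig())
    est = fr.poses[0].as_vector()
    assert abs(est[0] - (truth[0] + xs[gi])) <= 0.25 + 1e-9
    assert abs(est[3] - (truth[3] + ps[gj])) <= 0.5 + 1e-9


def test_penalty_separates_interpenetrating_start():
    spec = SceneSpec(
        seed=9, n_bones=2, detector_px=(336, 276), pixel_pitch_mm=0.16,
        bone_size_mm=12.0, bone_subdivisions=18,
    )
    scene = make_articulated_scene(spec)
    imgs = {
        vid: render_fluoro_image(
            model, scene.bones, scene.placement, noise_sigma=2.0,
            rng=np.random.default_rng([9, ord(vid)]),
        )
        for vid, model in scene.rig.views.items()
    }
    m = EdgeMatcher(scene.rig, scene.bones, imgs)
    # start the two bones pushed into each other
    mid = 0.5 * (scene.placement[0].translation + scene.placement[1].translation)
    inits = [
        Pose(*(0.6 * scene.placement[0].translation + 0.4 * mid)),
        Pose(*(0.6 * scene.placement[1].translation + 0.4 * mid)),
    ]
    fr = optimize_frame(m, inits, OptimizerConfig(strategy="sequential", cycles=2))
    rep = m.penetration(fr.poses)
    assert rep.D[0, 1] < 0.05


def test_registration_result_objective_consistency(small_scene):
    scene, imgs = small_scene
    m = EdgeMatcher(scene.rig, scene.bones, imgs)
    fr = optimize_frame(m, [scene.placement[0]], OptimizerConfig())
    assert fr.I == pytest.approx(m.objective(fr.poses).I, abs=1e-9)


def test_static_sequence_stationary(small_scene):
    scene, imgs = small_scene
    frames = [imgs, imgs, imgs]
    res = track_sequence(
        scene.rig, scene.bones, frames, [scene.placement[0]], OptimizerConfig()
    )
    p0 = res.frames[0].poses[0].as_vector()
    for fr in res.frames[1:]:
        d = np.abs(fr.poses[0].as_vector() - p0)
        assert d[:3].max() < 0.1 and d[3:].max() < 0.1


def test_optimizer_config_validation():
    with pytest.raises(ValueError):
        OptimizerConfig(step_size_sets=())
    with pytest.raises(ValueError):
        OptimizerConfig(step_size_sets=((1.0, -1.0),))
    with pytest.raises(ValueError):
        OptimizerConfig(strategy="global")
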
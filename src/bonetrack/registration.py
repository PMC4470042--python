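"""Edge-based 2D/3D registration objective and its optimisation.

The similarity of one bone is the sum over the two views of the
uncentred normalised dot product (cosine similarity) between the binary
edge-enhanced fluoroscopic image F and the graded dilated edge image V'
of the bone's virtual projection:

    S_i = (F_L . V'_L) / (|F_L| |V'_L|) + (F_R . V'_R) / (|F_R| |V'_R|)

Multi-bone scenes maximise the penetration-penalised objective

    I = sum_i ( S_i - sum_{j != i} mu * D_ij )

where D_ij is the penetration depth (mm) between bones i and j and
mu = 1000, so any interpenetration dominates the similarity (each
contacting pair is counted in both bones' terms).  The objective is
maximised by a quasi-Newton (BFGS) scheme whose gradients are central
finite differences evaluated with several step sizes, run
coarse-to-fine, which lets the optimiser escape the narrow capture
basin of thin edge maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .bone_model import BoneMesh, Pose, pose_to_matrix, transform_mesh
from .calibration import BiplanarRig, project
from .imaging import (
    VIRTUAL_FOREGROUND,
    EdgeImage,
    EdgeParams,
    _fill_triangles,
    make_F,
    make_Vprime,
)

__all__ = [
    "SimilarityScore",
    "PenetrationReport",
    "ObjectiveValue",
    "OptimizerConfig",
    "RegistrationResult",
    "similarity",
    "penetration_depth",
    "EdgeMatcher",
    "optimize_frame",
    "track_sequence",
]

MU_DEFAULT = 1000.0


@dataclass(frozen=True)
class SimilarityScore:
    left: float
    right: float

    @property
    def total(self) -> float:
        return self.left + self.right


@dataclass
class PenetrationReport:
    """Pairwise penetration depths (mm) and the penalty coefficient."""

    D: np.ndarray
    mu: float = MU_DEFAULT

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if not np.allclose(D, D.T) or np.any(D < 0) or np.any(np.diag(D) != 0):
            raise ValueError("D must be symmetric, non-negative, zero diagonal")
        self.D = D


@dataclass
class ObjectiveValue:
    I: float
    S: list[float]
    penalty: list[float]
    penetration: PenetrationReport | None = None


@dataclass
class OptimizerConfig:
    """Quasi-Newton settings.

    ``step_size_sets`` lists (translation mm, rotation deg) central
    finite-difference steps; by default each run starts from the previous
    set's solution (coarse-to-fine), and the solution with the largest
    final objective is returned.  Set ``chain_restarts`` False for
    independent restarts from the shared initial guess.
    """

    step_size_sets: tuple = (
        (3.0, 3.0),
        (1.0, 2.0),
        (0.3, 1.0),
        (0.1, 0.4),
        (0.1, 0.15),
    )
    max_iterations: int = 20
    gradient_tolerance: float = 1e-4
    parameter_tolerance: float = 1e-5
    chain_restarts: bool = True
    mu: float = MU_DEFAULT
    strategy: str = "joint"  # or "sequential" (per-bone cyclic)
    cycles: int = 2  # sequential only: passes over the bones
    coarse_dilation: bool = True  # widen the V' ramp to the FD step scale
    penalty_step_threshold: float = 0.5  # mm; penalty active once steps are finer
    max_restarts: int = 6  # jittered retries for bones with anomalously low S
    restart_similarity_fraction: float = 0.7  # restart if S < fraction * max(S)
    restart_jitter: tuple = (1.5, 1.5)  # mm, deg; grows every two attempts
    rotation_polish_attempts: int = 2  # rotation-jittered fine refinements
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.step_size_sets) == 0:
            raise ValueError("need at least one step-size set")
        if any(s <= 0 for pair in self.step_size_sets for s in pair):
            raise ValueError("finite-difference steps must be positive")
        if self.strategy not in ("joint", "sequential"):
            raise ValueError("strategy must be 'joint' or 'sequential'")


@dataclass
class FrameResult:
    poses: list[Pose]
    S: list[float]
    I: float
    converged: bool
    iterations: int
    best_step_set: tuple | None = None


@dataclass
class RegistrationResult:
    frames: list[FrameResult] = field(default_factory=list)
    bone_names: list[str] = field(default_factory=list)

    def pose(self, frame: int, bone: int) -> Pose:
        return self.frames[frame].poses[bone]

    def to_frame(self):
        """Trajectory table (frame, bone, x..psi, S, I, converged)."""
        import dataclasses as _dc

        import pandas as pd

        rows = []
        for f, fr in enumerate(self.frames):
            for b, pose in enumerate(fr.poses):
                name = self.bone_names[b] if self.bone_names else str(b)
                rows.append(
                    dict(
                        frame=f,
                        bone=name,
                        **_dc.asdict(pose),
                        S=fr.S[b],
                        I=fr.I,
                        converged=fr.converged,
                    )
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def _cosine(f: np.ndarray, v: np.ndarray) -> float:
    nf = np.sqrt(float(np.dot(f, f)))
    nv = np.sqrt(float(np.dot(v, v)))
    if nf == 0.0 or nv == 0.0:
        warnings.warn("zero-norm edge image: similarity term set to 0", stacklevel=3)
        return 0.0
    return float(np.dot(f, v)) / (nf * nv)


def similarity(
    F_L: EdgeImage, F_R: EdgeImage, Vp_L: EdgeImage, Vp_R: EdgeImage
) -> SimilarityScore:
    """Two-view cosine similarity between F and V' (uncentred, as defined)."""
    if F_L.shape != Vp_L.shape or F_R.shape != Vp_R.shape:
        raise ValueError("edge image shapes must match per view")
    return SimilarityScore(
        left=_cosine(F_L.pixels.ravel().astype(float), Vp_L.pixels.ravel().astype(float)),
        right=_cosine(F_R.pixels.ravel().astype(float), Vp_R.pixels.ravel().astype(float)),
    )


# ---------------------------------------------------------------------------
# penetration depth
# ---------------------------------------------------------------------------

def _surface_samples(mesh: BoneMesh) -> np.ndarray:
    """Vertices plus face centroids: deterministic dense surface sampling."""
    return np.vstack([mesh.vertices, mesh.vertices[mesh.faces].mean(axis=1)])


def penetration_depth(meshA: BoneMesh, meshB: BoneMesh) -> float:
    """Approximate penetration depth (mm) between two posed meshes.

    Bidirectional signed-distance sampling: the deepest surface sample of
    either mesh beneath the other's surface (0 if disjoint).  A bounding
    box reject makes the common disjoint case cheap.
    """
    if meshA.as_trimesh().area == 0 or meshB.as_trimesh().area == 0:
        raise ValueError("degenerate (zero-area) mesh")
    loA = meshA.vertices.min(axis=0)
    hiA = meshA.vertices.max(axis=0)
    loB = meshB.vertices.min(axis=0)
    hiB = meshB.vertices.max(axis=0)
    if np.any(hiA < loB) or np.any(hiB < loA):
        return 0.0
    from ._geometry import signed_distance

    depth = 0.0
    for src, tgt in ((meshA, meshB), (meshB, meshA)):
        pts = _surface_samples(src)
        # only samples inside the other's bounding box can penetrate
        lo, hi = tgt.vertices.min(axis=0), tgt.vertices.max(axis=0)
        near = np.all((pts >= lo) & (pts <= hi), axis=1)
        if not near.any():
            continue
        sd = signed_distance(pts[near], tgt.vertices, tgt.faces)
        depth = max(depth, float(sd.max()))
    return max(depth, 0.0)


class SDFGrid:
    """Signed-distance grid of a reference mesh (positive inside).

    Sampled by trilinear interpolation; used as the fast penetration
    proxy inside the optimisation loop.  Accuracy ~ half a voxel near the
    surface.
    """

    def __init__(self, mesh: BoneMesh, pitch: float = 0.4, pad: float = 3.0):
        tm = mesh.as_trimesh()
        lo = tm.bounds[0] - pad
        hi = tm.bounds[1] + pad
        shape = np.ceil((hi - lo) / pitch).astype(int) + 1
        vg = tm.voxelized(pitch).fill()
        occ = np.zeros(shape, bool)
        idx = np.round((vg.points - lo) / pitch).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        occ[tuple(idx[ok].T)] = True
        dist_out = ndi.distance_transform_edt(~occ) * pitch
        dist_in = ndi.distance_transform_edt(occ) * pitch
        self.sdf = dist_in - dist_out
        self.lo = lo
        self.pitch = pitch

    def query(self, pts: np.ndarray) -> np.ndarray:
        g = (np.atleast_2d(pts) - self.lo) / self.pitch
        return ndi.map_coordinates(self.sdf, g.T, order=1, mode="constant", cval=-1e3)


def _pair_penetration_grid(
    samplesA_world: np.ndarray,
    samplesB_world: np.ndarray,
    T_A: np.ndarray,
    T_B: np.ndarray,
    sdfA: SDFGrid,
    sdfB: SDFGrid,
) -> float:
    boxA = samplesA_world.min(axis=0), samplesA_world.max(axis=0)
    boxB = samplesB_world.min(axis=0), samplesB_world.max(axis=0)
    if np.any(boxA[1] < boxB[0]) or np.any(boxB[1] < boxA[0]):
        return 0.0
    TinvB = np.linalg.inv(T_B)
    la = samplesA_world @ TinvB[:3, :3].T + TinvB[:3, 3]
    d = float(sdfB.query(la).max())
    TinvA = np.linalg.inv(T_A)
    lb = samplesB_world @ TinvA[:3, :3].T + TinvA[:3, 3]
    d = max(d, float(sdfA.query(lb).max()))
    return max(d, 0.0)


# ---------------------------------------------------------------------------
# the matcher (per-frame objective)
# ---------------------------------------------------------------------------

class EdgeMatcher:
    """Objective evaluator for one biplanar frame.

    Precomputes the edge-enhanced fluoroscopic images F (and their norms)
    once; each evaluation renders a bone's silhouette in a cropped window
    around its projection, runs the virtual edge chain on the crop, and
    accumulates the similarity against the stored F.  Using the global
    norm of F makes the cropped computation identical to the full-image
    definition, since V' vanishes outside the crop.
    """

    MARGIN = 12  # px around the projected bbox: room for Canny + dilation

    def __init__(
        self,
        rig: BiplanarRig,
        bones: list[BoneMesh],
        images: dict[str, np.ndarray],
        params: EdgeParams | None = None,
        mu: float = MU_DEFAULT,
        use_sdf_grid: bool = True,
    ):
        self.rig = rig
        self.bones = bones
        self.params = params or EdgeParams()
        self.mu = mu
        self.F: dict[str, np.ndarray] = {}
        self.F_norm: dict[str, float] = {}
        for vid, model in rig.views.items():
            F = make_F(images[vid], self.params, vid).pixels.astype(np.float32)
            self.F[vid] = F
            self.F_norm[vid] = float(np.sqrt(F.sum()))  # binary: ||F|| = sqrt(count)
        self._sdf = (
            [SDFGrid(b) for b in bones] if (use_sdf_grid and len(bones) > 1) else None
        )
        self._samples = [_surface_samples(b) for b in bones]

    @property
    def px_per_mm(self) -> float:
        """Detector pixels per mm of object motion at the volume centre."""
        if not hasattr(self, "_px_per_mm"):
            disp = []
            for model in self.rig.views.values():
                o = project(model, np.zeros(3))
                for ax in np.eye(3):
                    disp.append(np.linalg.norm(project(model, ax) - o))
            self._px_per_mm = float(np.median(disp))
        return self._px_per_mm

    def stage_dilation(self, trans_step_mm: float, enabled: bool = True) -> int:
        """Ramp width for a search stage: wide enough to reach one FD step."""
        if not enabled:
            return self.params.dilation_iterations
        auto = int(np.ceil(trans_step_mm * self.px_per_mm))
        return max(self.params.dilation_iterations, auto)

    # -- rendering helpers ------------------------------------------------
    def _render_crop(self, view: str, bone: int, pose: Pose, margin: int | None = None):
        model = self.rig.views[view]
        mesh = self.bones[bone]
        posed_v = self._posed_vertices(bone, pose)
        w = np.hstack([posed_v, np.ones((len(posed_v), 1))]) @ model.P[2]
        if np.all(w <= 0):
            return None, None
        uv = project(model, posed_v)
        m = self.MARGIN if margin is None else margin
        c0 = max(int(np.floor(uv[:, 0].min())) - m, 0)
        c1 = min(int(np.ceil(uv[:, 0].max())) + m, model.image_width - 1)
        r0 = max(int(np.floor(uv[:, 1].min())) - m, 0)
        r1 = min(int(np.ceil(uv[:, 1].max())) + m, model.image_height - 1)
        if c1 <= c0 or r1 <= r0:
            return None, None
        h, wd = r1 - r0 + 1, c1 - c0 + 1
        rc = uv[:, ::-1] - np.array([r0, c0], dtype=float)
        tris = np.ascontiguousarray(rc[mesh.faces], dtype=np.float64)
        mask = _fill_triangles(h, wd, tris)
        return mask, (r0, c0)

    def _posed_vertices(self, bone: int, pose: Pose) -> np.ndarray:
        T = pose_to_matrix(pose)
        return self.bones[bone].vertices @ T[:3, :3].T + T[:3, 3]

    # -- objective terms --------------------------------------------------
    def bone_similarity(
        self, bone: int, pose: Pose, dilation_iterations: int | None = None
    ) -> SimilarityScore:
        dil = dilation_iterations or self.params.dilation_iterations
        terms = {}
        for vid in ("L", "R"):
            mask, off = self._render_crop(vid, bone, pose, margin=10 + dil)
            if mask is None or not mask.any():
                terms[vid] = 0.0
                continue
            vp = make_Vprime(
                mask.astype(np.float64) * VIRTUAL_FOREGROUND, self.params, dil
            )
            v = vp.pixels.astype(np.float32)
            nv = float(np.sqrt((v * v).sum()))
            if nv == 0.0 or self.F_norm[vid] == 0.0:
                terms[vid] = 0.0
                continue
            r0, c0 = off
            h, w = v.shape
            Fc = self.F[vid][r0 : r0 + h, c0 : c0 + w]
            terms[vid] = float((Fc * v).sum()) / (self.F_norm[vid] * nv)
        return SimilarityScore(left=terms["L"], right=terms["R"])

    def penetration(self, poses: list[Pose]) -> PenetrationReport:
        n = len(self.bones)
        D = np.zeros((n, n))
        if n > 1:
            Ts = [pose_to_matrix(p) for p in poses]
            sw = [
                self._samples[i] @ Ts[i][:3, :3].T + Ts[i][:3, 3] for i in range(n)
            ]
            for i in range(n):
                for j in range(i + 1, n):
                    if self._sdf is not None:
                        d = _pair_penetration_grid(
                            sw[i], sw[j], Ts[i], Ts[j], self._sdf[i], self._sdf[j]
                        )
                    else:
                        d = penetration_depth(
                            transform_mesh(self.bones[i], poses[i]),
                            transform_mesh(self.bones[j], poses[j]),
                        )
                    D[i, j] = D[j, i] = d
        return PenetrationReport(D=D, mu=self.mu)

    def objective(self, poses: list[Pose]) -> ObjectiveValue:
        S = [self.bone_similarity(i, p).total for i, p in enumerate(poses)]
        rep = self.penetration(poses)
        penalty = [self.mu * rep.D[i].sum() for i in range(len(poses))]
        return ObjectiveValue(
            I=float(sum(S) - sum(penalty)), S=S, penalty=penalty, penetration=rep
        )


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

def _fd_gradient(f, x: np.ndarray, steps: np.ndarray) -> np.ndarray:
    g = np.empty_like(x)
    for k in range(len(x)):
        e = np.zeros_like(x)
        e[k] = steps[k]
        g[k] = (f(x + e) - f(x - e)) / (2.0 * steps[k])
    return g


def _maximize(f, x0, steps, cfg: OptimizerConfig):
    """One BFGS run maximising f with central-difference gradients.

    Uses an Armijo backtracking line search (a single gradient per
    iteration): the finite-difference gradient is the dominant cost, and
    a strong-Wolfe search on this noisy, piecewise-flat objective would
    spend most of its evaluations re-differencing at trial points.
    """
    x = np.asarray(x0, dtype=float).copy()
    fx = f(x)
    best_x, best_val = x.copy(), fx
    nfev = 1
    H = np.diag(steps**2)  # initial inverse-Hessian scale per parameter
    g = _fd_gradient(f, x, steps)
    nfev += 2 * len(x)
    nit = 0
    for nit in range(1, cfg.max_iterations + 1):
        if np.max(np.abs(g) * steps) < cfg.gradient_tolerance:
            break
        p = H @ g  # ascent direction
        if not np.all(np.isfinite(p)) or np.dot(p, g) <= 0:
            p = (steps**2) * g
        def _backtrack(direction):
            # scale the first trial so its largest component ~ the FD step
            scale = np.max(np.abs(direction) / steps)
            alpha = 1.0 if scale <= 1.0 else 1.0 / scale
            for _ in range(6):
                x_t = x + alpha * direction
                f_t = f(x_t)
                if f_t > fx + 1e-4 * alpha * np.dot(g, direction):
                    return x_t, f_t, True
                alpha *= 0.5
            return x, fx, False

        x_new, f_new, improved = _backtrack(p)
        nfev += 6
        if not improved:
            # quasi-Newton direction rejected: reset and try steepest ascent
            H = np.diag(steps**2)
            p = (steps**2) * g
            x_new, f_new, improved = _backtrack(p)
            nfev += 6
        if not improved:
            break
        s = x_new - x
        g_new = _fd_gradient(f, x_new, steps)
        nfev += 2 * len(x)
        y = g_new - g  # note: ascent; curvature condition is s.y < 0
        sy = np.dot(s, y)
        if sy < -1e-12:
            rho = 1.0 / sy
            I_ = np.eye(len(x))
            V = I_ - rho * np.outer(s, y)
            H = V @ H @ V.T + abs(rho) * np.outer(s, s)
        x, fx, g = x_new, f_new, g_new
        if fx > best_val:
            best_val, best_x = fx, x.copy()
        if np.max(np.abs(s) / steps) < cfg.parameter_tolerance:
            break
    return best_x, best_val, nit, nfev


def _expand_steps(step_pair, n_params):
    t, r = step_pair
    one = np.array([t, t, t, r, r, r], dtype=float)
    return np.tile(one, n_params // 6)


def optimize_frame(
    matcher: EdgeMatcher,
    initial_poses: list[Pose],
    cfg: OptimizerConfig | None = None,
) -> FrameResult:
    """Register all bones of one frame starting from the given guesses.

    ``cfg.strategy = 'joint'`` optimises the 6N-parameter objective at
    once; ``'sequential'`` cycles over bones, optimising each bone's own
    terms with the others frozen (cheaper for many bones).  Each
    step-size set triggers one quasi-Newton run; runs are chained
    coarse-to-fine by default and the best final objective wins.
    """
    cfg = cfg or OptimizerConfig()
    n = len(matcher.bones)
    if len(initial_poses) != n:
        raise ValueError("one initial pose per bone is required")
    if cfg.strategy == "joint" or n == 1:
        poses, I, nit, ok, best_set = _optimize_joint(matcher, initial_poses, cfg)
    else:
        poses, I, nit, ok, best_set = _optimize_sequential(matcher, initial_poses, cfg)
    obj = matcher.objective(poses)
    return FrameResult(
        poses=poses,
        S=obj.S,
        I=obj.I,
        converged=ok,
        iterations=nit,
        best_step_set=best_set,
    )


def _stage_schedule(matcher, cfg):
    """Per step-size set: (steps pair, V' ramp width, penalty coefficient).

    Coarse stages widen the graded dilation to the finite-difference step
    scale so the similarity has gradient at the initial perturbation
    distance, and run without the penetration penalty (continuation);
    both reach their published operating values in the fine stages.
    """
    sched = []
    for t, r in cfg.step_size_sets:
        dil = matcher.stage_dilation(t, enabled=cfg.coarse_dilation)
        mu = cfg.mu if t <= cfg.penalty_step_threshold else 0.0
        sched.append(((t, r), dil, mu))
    return sched


def _optimize_joint(matcher, initial_poses, cfg):
    n = len(matcher.bones)
    x0 = np.concatenate([p.as_vector() for p in initial_poses])

    def make_f(dil, mu):
        def f(x):
            poses = [Pose.from_vector(x[6 * i : 6 * i + 6]) for i in range(n)]
            S = sum(
                matcher.bone_similarity(i, p, dilation_iterations=dil).total
                for i, p in enumerate(poses)
            )
            val = S
            if mu > 0 and n > 1:
                val -= mu * matcher.penetration(poses).D.sum()
            return val if np.isfinite(val) else -1e6

        return f

    best_x, best_I, total_nit, best_set = None, -np.inf, 0, None
    x_start = x0
    for step_pair, dil, mu in _stage_schedule(matcher, cfg):
        f = make_f(dil, mu)
        steps = _expand_steps(step_pair, 6 * n)
        x, I, nit, _ = _maximize(f, x_start, steps, cfg)
        total_nit += nit
        final = make_f(matcher.params.dilation_iterations, cfg.mu)(x)
        if final > best_I:
            best_I, best_x, best_set = final, x, step_pair
        if cfg.chain_restarts:
            x_start = x
    if best_x is None or not np.isfinite(best_I):
        raise RuntimeError("registration failed: objective non-finite for all restarts")
    poses = [Pose.from_vector(best_x[6 * i : 6 * i + 6]) for i in range(n)]
    return poses, best_I, total_nit, True, best_set


def _optimize_sequential(matcher, initial_poses, cfg):
    n = len(matcher.bones)
    poses = list(initial_poses)
    total_nit = 0
    best_set = None
    schedule = _stage_schedule(matcher, cfg)
    for cycle in range(cfg.cycles):
        # penalty continuation across cycles: bones are first registered on
        # similarity alone (their neighbours may still sit at wrong,
        # overlapping guesses), the last cycle enforces non-penetration
        penalized = cycle == cfg.cycles - 1
        for i in range(n):

            def make_f(dil, mu, i=i):
                def f(x):
                    trial = list(poses)
                    trial[i] = Pose.from_vector(x)
                    val = matcher.bone_similarity(
                        i, trial[i], dilation_iterations=dil
                    ).total
                    if mu > 0:
                        # the moving bone's pairs appear in both i's and
                        # j's terms of the double sum, hence the factor 2
                        val -= 2.0 * mu * matcher.penetration(trial).D[i].sum()
                    return val if np.isfinite(val) else -1e6

                return f

            f_ref = make_f(
                matcher.params.dilation_iterations, cfg.mu if penalized else 0.0
            )
            x_start = poses[i].as_vector()
            best_x, best_val = x_start, f_ref(x_start)
            for step_pair, dil, mu in schedule:
                f = make_f(dil, mu if penalized else 0.0)
                steps = _expand_steps(step_pair, 6)
                x, v, nit, _ = _maximize(f, x_start, steps, cfg)
                total_nit += nit
                v_ref = f_ref(x)
                if v_ref > best_val:
                    best_val, best_x, best_set = v_ref, x, step_pair
                if cfg.chain_restarts:
                    x_start = x
            poses[i] = Pose.from_vector(best_x)
    total_nit += _restart_low_similarity_bones(
        matcher, poses, initial_poses, schedule, cfg
    )
    total_nit += _rotation_polish(matcher, poses, schedule, cfg)
    I = matcher.objective(poses).I
    if not np.isfinite(I):
        raise RuntimeError("registration failed: objective non-finite for all restarts")
    return poses, I, total_nit, True, best_set


def _restart_low_similarity_bones(matcher, poses, initial_poses, schedule, cfg):
    """Retry bones whose similarity fell far below their neighbours'.

    In crowded scenes a bone occasionally locks onto a neighbour's
    contour; its final S is then well below the scene's best. Such
    bones are re-optimised from a few seeded jitters of their initial
    guess on similarity alone (best S wins), then refined with the
    penalty through the fine stages.
    """
    n = len(matcher.bones)
    if n < 2 or cfg.max_restarts < 1:
        return 0
    S = [matcher.bone_similarity(i, poses[i]).total for i in range(n)]
    threshold = cfg.restart_similarity_fraction * max(S)
    # a restart counts as captured only once it reaches the scene's best
    target = 0.85 * max(S)
    rng = np.random.default_rng(cfg.seed + 17)
    nit_total = 0
    jt, jr = cfg.restart_jitter
    for i in range(n):
        if S[i] >= threshold:
            continue
        best_x, best_S = poses[i].as_vector(), S[i]
        for attempt in range(cfg.max_restarts):
            scale = 1.0 + 0.5 * (attempt // 2)  # widen the search if stuck
            x = initial_poses[i].as_vector() + np.concatenate(
                [
                    rng.uniform(-jt * scale, jt * scale, 3),
                    rng.uniform(-jr * scale, jr * scale, 3),
                ]
            )
            for step_pair, dil, _mu in schedule:
                def f(xx, i=i, dil=dil):
                    return matcher.bone_similarity(
                        i, Pose.from_vector(xx), dilation_iterations=dil
                    ).total
                x, _v, nit, _ = _maximize(f, x, _expand_steps(step_pair, 6), cfg)
                nit_total += nit
            v = matcher.bone_similarity(i, Pose.from_vector(x)).total
            if v > best_S:
                best_S, best_x = v, x
                if v >= target:
                    break
        # penalised fine refinement of the recovered bone
        x = best_x
        for step_pair, dil, _mu in schedule[-2:]:
            def fpen(xx, i=i, dil=dil):
                trial = list(poses)
                trial[i] = Pose.from_vector(xx)
                val = matcher.bone_similarity(i, trial[i], dilation_iterations=dil).total
                return val - 2.0 * cfg.mu * matcher.penetration(trial).D[i].sum()
            x, _v, nit, _ = _maximize(fpen, x, _expand_steps(step_pair, 6), cfg)
            nit_total += nit
        poses[i] = Pose.from_vector(x)
    return nit_total


def _rotation_polish(matcher, poses, schedule, cfg):
    """Escape shallow rotation-only local optima.

    The similarity is far less sensitive to rotation than to translation
    (a degree moves contour pixels less than a millimetre does), so a
    bone can settle ~1 deg off with its translation converged. Each bone
    is re-refined through the fine stages from a few rotation-jittered
    copies of its solution; a candidate replaces it only if it improves
    both the similarity and the penalised per-bone objective.
    """
    if cfg.rotation_polish_attempts < 1:
        return 0
    n = len(matcher.bones)
    fine = schedule[-2:]
    rng = np.random.default_rng(cfg.seed + 29)
    nit_total = 0
    for i in range(n):
        def pen_val(x):
            trial = list(poses)
            trial[i] = Pose.from_vector(x)
            s = matcher.bone_similarity(i, trial[i]).total
            return s, s - 2.0 * cfg.mu * matcher.penetration(trial).D[i].sum()

        base = poses[i].as_vector()
        best_x = base
        best_S, best_pen = pen_val(base)
        for _ in range(cfg.rotation_polish_attempts):
            x = base.copy()
            x[3:] += rng.uniform(-1.2, 1.2, 3)
            for step_pair, dil, _mu in fine:
                def f(xx, i=i, dil=dil):
                    return matcher.bone_similarity(
                        i, Pose.from_vector(xx), dilation_iterations=dil
                    ).total
                x, _v, nit, _ = _maximize(f, x, _expand_steps(step_pair, 6), cfg)
                nit_total += nit
            s, p = pen_val(x)
            if s > best_S + 1e-6 and p > best_pen:
                best_S, best_pen, best_x = s, p, x
        poses[i] = Pose.from_vector(best_x)
    return nit_total


# ---------------------------------------------------------------------------
# sequential tracking
# ---------------------------------------------------------------------------

def track_sequence(
    rig: BiplanarRig,
    bones: list[BoneMesh],
    frames: list[dict[str, np.ndarray]],
    initial_poses: list[Pose],
    cfg: OptimizerConfig | None = None,
    params: EdgeParams | None = None,
    tracker=None,
    first_frame_cfg: OptimizerConfig | None = None,
) -> RegistrationResult:
    """Frame-by-frame registration of an image sequence.

    The first frame starts from the supplied (manual) poses; every later
    frame starts from the previous solution, composed with the rigid
    inter-frame delta estimated by the landmark ``tracker`` (an object
    with ``advance(frame_images, rig) -> list[4x4 | None]``) when one is
    configured.  A frame whose optimisation raises is recorded as
    unconverged and tracking continues from the last good poses.
    """
    cfg = cfg or OptimizerConfig()
    result = RegistrationResult(bone_names=[m.name for m in bones])
    guesses = list(initial_poses)
    for f, images in enumerate(frames):
        matcher = EdgeMatcher(rig, bones, images, params=params, mu=cfg.mu)
        if f > 0 and tracker is not None:
            deltas = tracker.advance(images, rig)
            prev = result.frames[-1].poses
            new_guesses = []
            for b, d in enumerate(deltas):
                if d is None:
                    new_guesses.append(prev[b])
                else:
                    T = d @ pose_to_matrix(prev[b])
                    from .bone_model import matrix_to_pose

                    new_guesses.append(matrix_to_pose(T))
            guesses = new_guesses
        use_cfg = first_frame_cfg if (f == 0 and first_frame_cfg is not None) else cfg
        try:
            fr = optimize_frame(matcher, guesses, use_cfg)
        except RuntimeError:
            warnings.warn(f"frame {f}: registration failed; carrying poses forward")
            fr = FrameResult(
                poses=list(guesses), S=[np.nan] * len(bones), I=np.nan,
                converged=False, iterations=0,
            )
        result.frames.append(fr)
        guesses = list(fr.poses)
    return result
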
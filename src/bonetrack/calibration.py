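"""Biplanar projection geometry: DLT calibration, projection, triangulation.

Each fluoroscopic view is modelled as an ideal point-source perspective
projection onto a flat panel, i.e. a 3x4 homogeneous matrix P mapping
world coordinates (mm) to pixel coordinates, up to scale.  P is estimated
from >= 6 non-coplanar 3D/2D marker correspondences by the direct linear
transformation (DLT) with Hartley-style normalization.  Two quasi-orthogonal
views form a rig; 3D points are recovered by linear DLT triangulation.

Pixel convention: origin at the centre of the top-left pixel, u (x) grows
rightward along columns, v (y) downward along rows, 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from skimage import transform as sktransform

__all__ = [
    "ProjectionModel",
    "BiplanarRig",
    "CalibrationObservation",
    "estimate_dlt",
    "project",
    "triangulate",
    "fit_homography",
    "correct_trapezoidal_distortion",
    "calibration_error",
    "save_rig",
    "load_rig",
]

_COPLANARITY_TOL = 1e-6  # relative singular-value threshold for degeneracy
_TRIANGULATION_COND_MAX = 1e10


@dataclass(frozen=True)
class ProjectionModel:
    """One view's 3x4 point-source projection (world mm -> image px)."""

    P: np.ndarray
    image_width: int
    image_height: int
    view_id: str = "L"

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (3, 4):
            raise ValueError("P must be 3x4")
        if np.linalg.matrix_rank(P) < 3:
            raise ValueError("projection matrix is rank deficient")
        object.__setattr__(self, "P", P)

    @property
    def source_position(self) -> np.ndarray:
        """3D position of the X-ray point source (right null space of P)."""
        _, _, Vt = np.linalg.svd(self.P)
        C = Vt[-1]
        if abs(C[3]) < 1e-12:
            raise ValueError("source at infinity: not a point-source model")
        return C[:3] / C[3]

    @property
    def principal_axis(self) -> np.ndarray:
        """Unit vector from the source toward the detector."""
        M = self.P[:, :3]
        axis = np.linalg.det(M) * M[2]
        return axis / np.linalg.norm(axis)

    def ray(self, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Back-projected ray through pixel uv: (source, unit direction)."""
        M = self.P[:, :3]
        d = np.linalg.solve(M, np.array([uv[0], uv[1], 1.0]))
        d = d / np.linalg.norm(d)
        if np.dot(d, self.principal_axis) < 0:
            d = -d
        return self.source_position, d


@dataclass(frozen=True)
class BiplanarRig:
    """Two calibrated views in a quasi-orthogonal arrangement."""

    left: ProjectionModel
    right: ProjectionModel
    world_frame_note: str = "origin at the centre of the measurement volume"

    def __post_init__(self) -> None:
        ang = self.interview_angle_deg
        if ang <= 30.0:
            warnings.warn(
                f"inter-view angle {ang:.1f} deg < 30 deg: triangulation will "
                "be poorly conditioned",
                stacklevel=2,
            )

    @property
    def interview_angle_deg(self) -> float:
        c = abs(np.dot(self.left.principal_axis, self.right.principal_axis))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    @property
    def views(self) -> dict[str, ProjectionModel]:
        return {"L": self.left, "R": self.right}


@dataclass
class CalibrationObservation:
    """3D marker coordinates with their detected pixels in one view."""

    points3d: np.ndarray  # (N, 3) mm, calibration-object frame
    points2d: np.ndarray  # (N, 2) px
    view_id: str = "L"
    image_width: int = 672
    image_height: int = 552

    def __post_init__(self) -> None:
        self.points3d = np.atleast_2d(np.asarray(self.points3d, dtype=float))
        self.points2d = np.atleast_2d(np.asarray(self.points2d, dtype=float))
        if len(self.points3d) != len(self.points2d):
            raise ValueError("points3d and points2d must pair up")


# ---------------------------------------------------------------------------
# DLT estimation
# ---------------------------------------------------------------------------

def _normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    return (pts - c) * s, T


def _normalize_3d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    s = np.sqrt(3.0) / max(d, 1e-12)
    U = np.eye(4)
    U[:3, :3] *= s
    U[:3, 3] = -s * c
    return (pts - c) * s, U


def _check_not_coplanar(points3d: np.ndarray) -> None:
    centered = points3d - points3d.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < _COPLANARITY_TOL * max(sv[0], 1e-12):
        raise ValueError("degenerate configuration: calibration markers are coplanar")


def estimate_dlt(obs: CalibrationObservation) -> ProjectionModel:
    """Least-squares DLT fit of a 3x4 projection from point correspondences.

    The homogeneous system is solved by SVD with the unit-norm constraint
    fixing the scale (11 free parameters); both point sets are centred and
    isotropically scaled first for conditioning.
    """
    X, uv = obs.points3d, obs.points2d
    if len(X) < 6:
        raise ValueError("insufficient correspondences: DLT needs at least 6 points")
    _check_not_coplanar(X)
    Xn, U = _normalize_3d(X)
    uvn, T = _normalize_2d(uv)
    n = len(X)
    Xh = np.hstack([Xn, np.ones((n, 1))])
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -uvn[:, [0]] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -uvn[:, [1]] * Xh
    _, _, Vt = np.linalg.svd(A)
    Pn = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(T) @ Pn @ U
    P = P / np.linalg.norm(P)
    # fix the scale sign: points in front of the source get positive depth
    w = np.hstack([X, np.ones((n, 1))]) @ P[2]
    if np.median(w) < 0:
        P = -P
    return ProjectionModel(
        P=P,
        image_width=obs.image_width,
        image_height=obs.image_height,
        view_id=obs.view_id,
    )


def refine_dlt_nonlinear(model: ProjectionModel, obs: CalibrationObservation) -> ProjectionModel:
    """Nonlinear least-squares refinement of the reprojection error.

    Used as an independent cross-check of the algebraic DLT solution.
    """

    def resid(p):
        P = p.reshape(3, 4)
        uvh = np.hstack([obs.points3d, np.ones((len(obs.points3d), 1))]) @ P.T
        uv = uvh[:, :2] / uvh[:, [2]]
        return (uv - obs.points2d).ravel()

    res = optimize.least_squares(resid, model.P.ravel(), method="lm")
    P = res.x.reshape(3, 4)
    return ProjectionModel(
        P=P / np.linalg.norm(P),
        image_width=model.image_width,
        image_height=model.image_height,
        view_id=model.view_id,
    )


def reprojection_error(model: ProjectionModel, obs: CalibrationObservation) -> np.ndarray:
    """Per-marker reprojection error (px)."""
    uv = project(model, obs.points3d)
    return np.linalg.norm(uv - obs.points2d, axis=1)


# ---------------------------------------------------------------------------
# projection and triangulation
# ---------------------------------------------------------------------------

def project(model: ProjectionModel, point3d: np.ndarray) -> np.ndarray:
    """Project world point(s) (mm) to pixel coordinates via P.

    Accepts a single (3,) point or an (N, 3) array.
    """
    pts = np.atleast_2d(np.asarray(point3d, dtype=float))
    ph = np.hstack([pts, np.ones((len(pts), 1))]) @ model.P.T
    w = ph[:, 2]
    if np.any(np.abs(w) < 1e-9 * np.abs(ph[:, :2]).max(initial=1.0)):
        raise ValueError("point at infinity for this view (homogeneous w ~ 0)")
    uv = ph[:, :2] / w[:, None]
    return uv[0] if np.ndim(point3d) == 1 else uv


def triangulate(
    rig: BiplanarRig, uv_left: np.ndarray, uv_right: np.ndarray
) -> tuple[np.ndarray, float]:
    """Linear DLT triangulation of one point from its two pixel positions.

    Returns (point_mm, miss_distance_mm) where the miss distance is the
    shortest gap between the two back-projected rays (a quality measure;
    zero for exact correspondences).
    """
    uv_l = np.asarray(uv_left, dtype=float)
    uv_r = np.asarray(uv_right, dtype=float)
    for uv, m in ((uv_l, rig.left), (uv_r, rig.right)):
        if not (
            -0.5 <= uv[0] <= m.image_width - 0.5 and -0.5 <= uv[1] <= m.image_height - 0.5
        ):
            warnings.warn(
                f"pixel {uv} outside detector of view {m.view_id}", stacklevel=2
            )
    A = np.vstack(
        [
            uv_l[0] * rig.left.P[2] - rig.left.P[0],
            uv_l[1] * rig.left.P[2] - rig.left.P[1],
            uv_r[0] * rig.right.P[2] - rig.right.P[0],
            uv_r[1] * rig.right.P[2] - rig.right.P[1],
        ]
    )
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[0] / max(sv[-2], 1e-300) > _TRIANGULATION_COND_MAX:
        raise ValueError("ill-conditioned triangulation: rays are near parallel")
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-12:
        raise ValueError("ill-conditioned triangulation: point at infinity")
    X = Xh[:3] / Xh[3]
    miss = _ray_miss_distance(rig, uv_l, uv_r)
    return X, miss


def _ray_miss_distance(rig: BiplanarRig, uv_l, uv_r) -> float:
    o1, d1 = rig.left.ray(uv_l)
    o2, d2 = rig.right.ray(uv_r)
    n = np.cross(d1, d2)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        return float(np.linalg.norm(np.cross(o2 - o1, d1)))
    return float(abs(np.dot(o2 - o1, n / nn)))


# ---------------------------------------------------------------------------
# trapezoidal distortion
# ---------------------------------------------------------------------------

def fit_homography(src_pts: np.ndarray, dst_pts: np.ndarray) -> np.ndarray:
    """3x3 plane homography mapping src to dst, from >= 4 correspondences."""
    src = np.asarray(src_pts, dtype=float)
    dst = np.asarray(dst_pts, dtype=float)
    if len(src) < 4:
        raise ValueError("homography needs at least 4 correspondences")
    try:
        tf = sktransform.ProjectiveTransform.from_estimate(src, dst)
        if not tf:
            raise ValueError("homography estimation failed")
    except AttributeError:  # older scikit-image
        tf = sktransform.ProjectiveTransform()
        if not tf.estimate(src, dst):
            raise ValueError("homography estimation failed")
    return tf.params / tf.params[2, 2]


def correct_trapezoidal_distortion(image: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Undo a linear trapezoidal (keystone) distortion.

    ``H`` maps ideal pixel coordinates (u, v) to observed ones; the output
    is the input resampled under H^-1 with bilinear interpolation,
    out-of-bounds pixels set to 0.  Identity H returns the input unchanged.
    """
    H = np.asarray(H, dtype=float)
    if abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("distortion homography is not invertible")
    if np.allclose(H / H[2, 2], np.eye(3)):
        return image.copy()
    # skimage warp uses (col, row) == (u, v) for ProjectiveTransform
    tf = sktransform.ProjectiveTransform(matrix=H)
    out = sktransform.warp(
        image.astype(float), tf, order=1, cval=0.0, preserve_range=True
    )
    return out.astype(image.dtype) if np.issubdtype(image.dtype, np.integer) else out


# ---------------------------------------------------------------------------
# calibration quality
# ---------------------------------------------------------------------------

def calibration_error(
    rig: BiplanarRig,
    points3d_true: np.ndarray,
    uv_left: np.ndarray,
    uv_right: np.ndarray,
) -> tuple[float, float]:
    """Mean and SD of 3D triangulated marker error (mm).

    Each marker, seen in both views, is triangulated from its detected
    pixel positions and compared with its known 3D position.
    """
    X = np.atleast_2d(np.asarray(points3d_true, dtype=float))
    uvl = np.atleast_2d(np.asarray(uv_left, dtype=float))
    uvr = np.atleast_2d(np.asarray(uv_right, dtype=float))
    ok = np.all(np.isfinite(uvl), axis=1) & np.all(np.isfinite(uvr), axis=1)
    if not ok.any():
        raise ValueError("no markers visible in both views")
    errs = []
    for xi, li, ri in zip(X[ok], uvl[ok], uvr[ok]):
        Xhat, _ = triangulate(rig, li, ri)
        errs.append(np.linalg.norm(Xhat - xi))
    errs = np.asarray(errs)
    return float(errs.mean()), float(errs.std(ddof=1) if len(errs) > 1 else 0.0)


# ---------------------------------------------------------------------------
# rig I/O
# ---------------------------------------------------------------------------

def save_rig(rig: BiplanarRig, path, distortion: dict | None = None) -> None:
    payload = {
        "world_frame_note": rig.world_frame_note,
        "views": {
            vid: {
                "P": m.P.ravel().tolist(),
                "image_width": m.image_width,
                "image_height": m.image_height,
            }
            for vid, m in rig.views.items()
        },
    }
    if distortion:
        payload["distortion"] = {k: np.asarray(v).tolist() for k, v in distortion.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_rig(path) -> BiplanarRig:
    with open(path) as fh:
        payload = json.load(fh)
    views = {}
    for vid, d in payload["views"].items():
        views[vid] = ProjectionModel(
            P=np.asarray(d["P"], dtype=float).reshape(3, 4),
            image_width=int(d["image_width"]),
            image_height=int(d["image_height"]),
            view_id=vid,
        )
    return BiplanarRig(
        left=views["L"],
        right=views["R"],
        world_frame_note=payload.get("world_frame_note", ""),
    )


def observations_from_csv(path) -> dict[str, CalibrationObservation]:
    """Read marker correspondences (marker_id, X, Y, Z, view, u, v) per view."""
    df = pd.read_csv(path)
    out = {}
    for vid, grp in df.groupby("view"):
        out[str(vid)] = CalibrationObservation(
            points3d=grp[["X", "Y", "Z"]].to_numpy(float),
            points2d=grp[["u", "v"]].to_numpy(float),
            view_id=str(vid),
        )
    return out
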
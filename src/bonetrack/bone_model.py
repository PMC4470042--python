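"""Bone surface meshes, anatomical coordinate frames and 6-DOF poses.

A bone is represented by a triangle surface mesh in millimetres together
with a small set of named anatomical landmarks.  The anatomical frame of a
bone has its origin at the area-weighted surface centroid of the mesh and
axes built from the landmarks (x ~ anteroposterior, y ~ mediolateral,
z ~ dorsoplantar).  Orientations are parameterised as intrinsic y-x-z
Euler angles (phi about y: plantarflexion-dorsiflexion, theta about x:
inversion-eversion, psi about z: adduction-abduction), in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial.transform import Rotation

__all__ = [
    "BoneMesh",
    "AnatomicalFrame",
    "Pose",
    "load_mesh",
    "write_mesh",
    "load_landmarks",
    "build_anatomical_frame",
    "pose_to_matrix",
    "matrix_to_pose",
    "compose_pose",
    "relative_pose",
    "transform_mesh",
]

_MERGE_TOL = 1e-6  # mm; duplicate vertices closer than this are merged


@dataclass
class BoneMesh:
    """Triangle surface model of one bone, coordinates in mm."""

    name: str
    vertices: np.ndarray  # (N, 3) float
    faces: np.ndarray  # (M, 3) int, CCW outward
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces index nonexistent vertices")
        if len(self.faces) == 0:
            raise ValueError(f"mesh '{self.name}' has zero faces")

    # -- geometry ---------------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @property
    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid (mm)."""
        tri = self.vertices[self.faces]  # (M, 3, 3)
        ctr = tri.mean(axis=1)
        area = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        return (ctr * area[:, None]).sum(axis=0) / area.sum()

    def boundary_edge_fraction(self) -> float:
        """Fraction of edges belonging to exactly one face (0 = closed)."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return float((counts == 1).sum() / len(counts))

    def check_watertightness(self, max_boundary_fraction: float = 0.05) -> bool:
        frac = self.boundary_edge_fraction()
        if frac >= max_boundary_fraction:
            warnings.warn(
                f"mesh '{self.name}': {frac:.1%} boundary edges; penetration "
                "tests may be unreliable",
                stacklevel=2,
            )
            return False
        return True


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin (mesh centroid) and orthonormal axes of a bone."""

    origin: np.ndarray
    R: np.ndarray  # columns: x (AP), y (ML), z (DP) axes

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("frame rotation is not a proper rotation")


@dataclass(frozen=True)
class Pose:
    """Rigid pose: translation (mm) and intrinsic y-x-z Euler angles (deg).

    phi rotates about y, theta about x, psi about z, applied in that order
    about the body-fixed axes: R = R_y(phi) R_x(theta) R_z(psi).
    """

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.phi, self.theta, self.psi], dtype=float)

    def as_vector(self) -> np.ndarray:
        """(x, y, z, phi, theta, psi) as a flat array."""
        return np.array([self.x, self.y, self.z, self.phi, self.theta, self.psi])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "Pose":
        v = np.asarray(v, dtype=float)
        return cls(*v[:6])


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

def load_mesh(path, name: str | None = None, landmarks_csv=None) -> BoneMesh:
    """Load an STL or PLY mesh; duplicate vertices are merged (tol 1e-6 mm)."""
    tm = trimesh.load_mesh(path, process=False)
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"no triangle faces found in {path}")
    tm.merge_vertices(digits_vertex=6)
    mesh = BoneMesh(
        name=name or getattr(path, "stem", str(path)).split("/")[-1].split(".")[0],
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
    )
    mesh.check_watertightness()
    if landmarks_csv is not None:
        lms = load_landmarks(landmarks_csv)
        mesh.landmarks = lms.get(mesh.name, lms.get(None, {}))
    return mesh


def write_mesh(mesh: BoneMesh, path) -> None:
    mesh.as_trimesh().export(path)


def load_landmarks(path) -> dict:
    """Read a landmark CSV (bone, landmark_name, X, Y, Z) grouped by bone."""
    df = pd.read_csv(path)
    out: dict = {}
    for _, row in df.iterrows():
        bone = row.get("bone", None)
        out.setdefault(bone, {})[row["landmark_name"]] = np.array(
            [row["X"], row["Y"], row["Z"]], dtype=float
        )
    return out


# ---------------------------------------------------------------------------
# anatomical frames
# ---------------------------------------------------------------------------

def build_anatomical_frame(mesh: BoneMesh) -> AnatomicalFrame:
    """Anatomical frame from >= 3 non-collinear landmarks.

    The first two landmarks define a provisional x axis, the third supplies
    the plane whose normal becomes z; y completes the right-handed triad
    (Gram-Schmidt).  The origin is always the mesh surface centroid.
    """
    if len(mesh.landmarks) < 3:
        raise ValueError("anatomical frame requires at least 3 landmarks")
    pts = [np.asarray(p, dtype=float) for p in mesh.landmarks.values()]
    l1, l2, l3 = pts[0], pts[1], pts[2]
    e1 = l2 - l1
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        raise ValueError("first two landmarks coincide")
    e1 = e1 / n1
    n = np.cross(e1, l3 - l1)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("landmarks are collinear; frame undefined")
    e3 = n / nn
    e2 = np.cross(e3, e1)
    R = np.column_stack([e1, e2, e3])
    return AnatomicalFrame(origin=mesh.centroid, R=R)


# ---------------------------------------------------------------------------
# Euler poses
# ---------------------------------------------------------------------------

def _rotation(pose: Pose) -> np.ndarray:
    # intrinsic y-x-z: uppercase seq in scipy
    return Rotation.from_euler(
        "YXZ", [pose.phi, pose.theta, pose.psi], degrees=True
    ).as_matrix()


def pose_to_matrix(pose: Pose) -> np.ndarray:
    """4x4 homogeneous rigid transform [R | t] of a pose."""
    T = np.eye(4)
    T[:3, :3] = _rotation(pose)
    T[:3, 3] = pose.translation
    return T


def matrix_to_pose(T: np.ndarray) -> Pose:
    """Inverse of :func:`pose_to_matrix`; theta branch in [-90, 90] deg.

    At gimbal lock (|theta| = 90 deg) psi is set to 0 and phi absorbs the
    remaining rotation (a warning is emitted).
    """
    T = np.asarray(T, dtype=float)
    R = T[:3, :3]
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("transform is not rigid")
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "always", message=".*Gimbal lock.*", category=UserWarning
        )
        phi, theta, psi = Rotation.from_matrix(R).as_euler("YXZ", degrees=True)
    # map angles into (-180, 180]
    wrap = lambda a: a - 360.0 * np.ceil((a - 180.0) / 360.0)
    return Pose(*T[:3, 3], wrap(phi), wrap(theta), wrap(psi))


def compose_pose(parent: Pose, local: Pose) -> Pose:
    """Pose of T_parent @ T_local."""
    return matrix_to_pose(pose_to_matrix(parent) @ pose_to_matrix(local))


def relative_pose(pose_child: Pose, pose_parent: Pose) -> Pose:
    """Pose of the child expressed in the parent's frame."""
    Tp = pose_to_matrix(pose_parent)
    Tc = pose_to_matrix(pose_child)
    return matrix_to_pose(np.linalg.inv(Tp) @ Tc)


def transform_mesh(mesh: BoneMesh, pose: Pose, about: np.ndarray | None = None) -> BoneMesh:
    """Apply a pose to a mesh: rotate about its centroid, then translate.

    Landmarks and marker points are transformed identically.  ``about``
    overrides the rotation centre (defaults to the surface centroid).
    """
    c = mesh.centroid if about is None else np.asarray(about, dtype=float)
    R = _rotation(pose)
    t = pose.translation

    def xf(p):
        return (np.asarray(p) - c) @ R.T + c + t

    return replace(
        mesh,
        vertices=xf(mesh.vertices),
        faces=mesh.faces.copy(),
        landmarks={k: xf(v) for k, v in mesh.landmarks.items()},
        markers={k: xf(v) for k, v in mesh.markers.items()},
    )


def pose_world_transform(pose: Pose, origin: np.ndarray | None = None) -> np.ndarray:
    """4x4 world transform of a bone posed about ``origin`` (default 0).

    Equivalent to translate(-origin) -> rotate -> translate(origin + t).
    """
    if origin is None:
        return pose_to_matrix(pose)
    o = np.asarray(origin, dtype=float)
    T = np.eye(4)
    R = _rotation(pose)
    T[:3, :3] = R
    T[:3, 3] = o + pose.translation - R @ o
    return T
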
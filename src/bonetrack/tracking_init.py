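"""Landmark template matching between consecutive frames.

Small (30x30 px) windows around bony landmarks are matched from one
frame to the next by normalised cross-correlation in both views; matched
positions are triangulated to 3D, and the rigid motion of each bone's
landmark set (orthogonal Procrustes) supplies the initial pose guess for
the next frame's registration.  Templates are re-extracted at the
matched position after every frame so slow appearance changes do not
accumulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import feature
from scipy.spatial.transform import Rotation

from .calibration import BiplanarRig, triangulate

__all__ = [
    "TemplatePatch",
    "LandmarkTrack",
    "extract_template",
    "match_template",
    "update_template",
    "landmarks_to_3d",
    "estimate_pose_delta",
    "TemplateTracker",
]

TEMPLATE_SIZE = 30  # px; window centre = top-left + (TEMPLATE_SIZE/2 - 0.5)
DEFAULT_SEARCH_RADIUS = 40  # px
DEFAULT_CORRELATION_FLOOR = 0.5


@dataclass
class TemplatePatch:
    """One landmark's 30x30 intensity window in one view."""

    pixels: np.ndarray
    center: tuple[float, float]  # (u, v) in the source frame
    view_id: str
    landmark_name: str

    def __post_init__(self) -> None:
        if self.pixels.shape != (TEMPLATE_SIZE, TEMPLATE_SIZE):
            raise ValueError(f"template must be {TEMPLATE_SIZE}x{TEMPLATE_SIZE}")


@dataclass
class LandmarkTrack:
    """Per-frame pixel positions, correlations and 3D points of landmarks."""

    positions: dict = field(default_factory=dict)  # (frame, name, view) -> (u, v)
    correlations: dict = field(default_factory=dict)  # (frame, name, view) -> r
    points3d: dict = field(default_factory=dict)  # (frame, name) -> (xyz, miss)


def _extract_window(img: np.ndarray, center_uv) -> np.ndarray:
    h = TEMPLATE_SIZE // 2
    c = int(round(center_uv[0] - (h - 0.5)))
    r = int(round(center_uv[1] - (h - 0.5)))
    if r < 0 or c < 0 or r + TEMPLATE_SIZE > img.shape[0] or c + TEMPLATE_SIZE > img.shape[1]:
        raise ValueError("template window extends outside the image")
    return img[r : r + TEMPLATE_SIZE, c : c + TEMPLATE_SIZE].astype(float)


def extract_template(
    img: np.ndarray, center_uv, view_id: str, landmark_name: str
) -> TemplatePatch:
    """Cut a 30x30 template window centred on (u, v).

    The stored centre is the actual centre of the extracted integer
    window (the requested centre snapped to the pixel grid).
    """
    h = TEMPLATE_SIZE // 2
    c = int(round(center_uv[0] - (h - 0.5)))
    r = int(round(center_uv[1] - (h - 0.5)))
    return TemplatePatch(
        pixels=_extract_window(img, (c + h - 0.5, r + h - 0.5)),
        center=(c + h - 0.5, r + h - 0.5),
        view_id=view_id,
        landmark_name=landmark_name,
    )


def _parabolic_refine(score: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Sub-pixel peak via 1D parabola fits along each axis."""
    r, c = peak
    dr = dc = 0.0
    if 0 < r < score.shape[0] - 1:
        a, b, cc = score[r - 1, c], score[r, c], score[r + 1, c]
        den = a - 2 * b + cc
        if den < 0:
            dr = float(np.clip(0.5 * (a - cc) / den, -0.5, 0.5))
    if 0 < c < score.shape[1] - 1:
        a, b, cc = score[r, c - 1], score[r, c], score[r, c + 1]
        den = a - 2 * b + cc
        if den < 0:
            dc = float(np.clip(0.5 * (a - cc) / den, -0.5, 0.5))
    return dr, dc


def match_template(
    img: np.ndarray,
    patch: TemplatePatch,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    correlation_floor: float = DEFAULT_CORRELATION_FLOOR,
) -> tuple[tuple[float, float], float, bool]:
    """Locate the template in a new frame by normalised cross-correlation.

    The search window spans the previous centre +/- ``search_radius``
    (clipped to the image with a warning).  Returns ((u, v), correlation,
    confident) with parabolic sub-pixel refinement of the NCC peak; the
    match is flagged unconfident below ``correlation_floor``.
    """
    half = TEMPLATE_SIZE // 2
    u0, v0 = patch.center
    r0 = int(round(v0 - (half - 0.5))) - search_radius
    c0 = int(round(u0 - (half - 0.5))) - search_radius
    r1 = r0 + TEMPLATE_SIZE + 2 * search_radius
    c1 = c0 + TEMPLATE_SIZE + 2 * search_radius
    if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
        warnings.warn("search window clipped to image bounds", stacklevel=2)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, img.shape[0]), min(c1, img.shape[1])
    window = img[r0:r1, c0:c1].astype(float)
    score = feature.match_template(window, patch.pixels, pad_input=False)
    peak = np.unravel_index(np.argmax(score), score.shape)
    corr = float(score[peak])
    dr, dc = _parabolic_refine(score, peak)
    # match position of the patch centre in the full image
    v = r0 + peak[0] + dr + (half - 0.5)
    u = c0 + peak[1] + dc + (half - 0.5)
    return (float(u), float(v)), corr, corr >= correlation_floor


def update_template(
    img: np.ndarray, position_uv, view_id: str, landmark_name: str
) -> TemplatePatch:
    """Re-extract the template at the matched position in the new frame."""
    return extract_template(img, position_uv, view_id, landmark_name)


def landmarks_to_3d(
    rig: BiplanarRig, positions: dict[str, dict[str, tuple[float, float]]]
) -> dict[str, tuple[np.ndarray, float]]:
    """Triangulate landmarks matched in both views.

    ``positions`` maps landmark name -> {view: (u, v)}; names missing a
    view are skipped with a warning.  Returns name -> (xyz mm, ray miss
    distance mm).
    """
    out = {}
    for name, per_view in positions.items():
        if "L" not in per_view or "R" not in per_view:
            warnings.warn(f"landmark {name!r} seen in one view only; skipped")
            continue
        X, miss = triangulate(rig, per_view["L"], per_view["R"])
        out[name] = (X, miss)
    return out


def estimate_pose_delta(
    p3d_prev: np.ndarray, p3d_curr: np.ndarray
) -> np.ndarray:
    """Rigid transform (4x4) mapping previous landmark positions to current.

    Least-squares orthogonal Procrustes (Kabsch) with the proper-rotation
    constraint for >= 3 non-collinear points; 1-2 points fall back to the
    mean translation; empty input returns identity with a warning.
    """
    A = np.atleast_2d(np.asarray(p3d_prev, dtype=float))
    B = np.atleast_2d(np.asarray(p3d_curr, dtype=float))
    T = np.eye(4)
    if A.size == 0:
        warnings.warn("no common landmarks: identity motion assumed")
        return T
    if len(A) != len(B):
        raise ValueError("landmark sets must pair up")
    if len(A) < 3:
        T[:3, 3] = B.mean(axis=0) - A.mean(axis=0)
        return T
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    sv = np.linalg.svd(A0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):  # collinear: rotation ambiguous
        T[:3, 3] = cb - ca
        return T
    R, _ = Rotation.align_vectors(B0, A0)
    Rm = R.as_matrix()
    T[:3, :3] = Rm
    T[:3, 3] = cb - Rm @ ca
    return T


class TemplateTracker:
    """Tracks a set of bony landmark templates across a biplanar sequence.

    Initialised from the first frame's images and the (manually defined)
    landmark pixel positions per view; :meth:`advance` matches all
    templates in the next frame pair, triangulates them, and returns one
    rigid 4x4 inter-frame motion per bone (None for bones without enough
    confident landmarks).  Templates are updated after every frame.
    """

    def __init__(
        self,
        frame0_images: dict[str, np.ndarray],
        landmark_pixels: dict[str, dict[str, tuple[float, float]]],
        bone_of_landmark: dict[str, str],
        bone_names: list[str],
        rig: BiplanarRig,
        search_radius: int = DEFAULT_SEARCH_RADIUS,
        correlation_floor: float = DEFAULT_CORRELATION_FLOOR,
    ):
        self.bone_names = list(bone_names)
        self.bone_of_landmark = dict(bone_of_landmark)
        self.search_radius = search_radius
        self.correlation_floor = correlation_floor
        self.templates: dict[tuple[str, str], TemplatePatch] = {}
        self.track = LandmarkTrack()
        self._frame = 0
        positions = {}
        for name, per_view in landmark_pixels.items():
            positions[name] = {}
            for vid, uv in per_view.items():
                try:
                    self.templates[(name, vid)] = extract_template(
                        frame0_images[vid], uv, vid, name
                    )
                except ValueError:
                    warnings.warn(f"landmark {name!r} too close to the border in {vid}")
                    continue
                positions[name][vid] = uv
                self.track.positions[(0, name, vid)] = uv
                self.track.correlations[(0, name, vid)] = 1.0
        self._prev3d = {}
        for n, (X, miss) in landmarks_to_3d(rig, positions).items():
            self._prev3d[n] = X
            self.track.points3d[(0, n)] = (X, miss)

    def advance(
        self, frame_images: dict[str, np.ndarray], rig: BiplanarRig
    ) -> list[np.ndarray | None]:
        """Match templates in the next frame; per-bone rigid deltas."""
        self._frame += 1
        f = self._frame
        positions: dict[str, dict[str, tuple[float, float]]] = {}
        for (name, vid), patch in list(self.templates.items()):
            (u, v), corr, ok = match_template(
                frame_images[vid], patch, self.search_radius, self.correlation_floor
            )
            self.track.positions[(f, name, vid)] = (u, v)
            self.track.correlations[(f, name, vid)] = corr
            if not ok:
                continue
            positions.setdefault(name, {})[vid] = (u, v)
            try:
                self.templates[(name, vid)] = update_template(
                    frame_images[vid], (u, v), vid, name
                )
            except ValueError:
                pass  # drifted to the border; keep the old template
        curr3d = {}
        for n, (X, miss) in landmarks_to_3d(rig, positions).items():
            curr3d[n] = X
            self.track.points3d[(f, n)] = (X, miss)
        deltas: list[np.ndarray | None] = []
        for bone in self.bone_names:
            names = [
                n
                for n in curr3d
                if self.bone_of_landmark.get(n) == bone and n in self._prev3d
            ]
            if not names:
                deltas.append(None)
                continue
            prev = np.array([self._prev3d[n] for n in names])
            curr = np.array([curr3d[n] for n in names])
            deltas.append(estimate_pose_delta(prev, curr))
        self._prev3d.update(curr3d)
        return deltas
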
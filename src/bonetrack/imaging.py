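"""2D image operators for edge-based registration.

Implements the edge-processing chain applied to both measured and
virtually projected images: Gaussian smoothing, Canny edge extraction,
edge-segment length filtering, graded dilation, and silhouette rendering
of posed bone meshes through a calibrated projection.

Naming follows the usual convention for this family of methods:
``F`` is the edge-enhanced fluoroscopic image (binary), ``V`` the
edge-enhanced virtual projection, and ``V'`` the graded dilation of V
that gives the similarity measure a capture basin around the contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage as ndi
from skimage import feature, measure

from .bone_model import BoneMesh, Pose, transform_mesh
from .calibration import ProjectionModel, project

__all__ = [
    "EdgeParams",
    "EdgeImage",
    "gaussian_smooth",
    "canny_edges",
    "filter_edge_segments",
    "dilate_graded",
    "render_virtual_projection",
    "make_F",
    "make_Vprime",
]

# internal smoothing used by the Canny operator itself (its thresholds are
# on the Sobel gradient magnitude of the image smoothed at this scale)
_CANNY_SIGMA = 1.0

VIRTUAL_FOREGROUND = 1500.0  # 16-bit-scale intensity of rendered silhouettes


@dataclass
class EdgeParams:
    """Edge-chain parameters.

    Canny thresholds are on the Sobel gradient-magnitude scale of the
    underlying 8-bit (fluoroscopic) or 16-bit (virtual) intensities; the
    per-view fluoroscopic defaults and both length cutoffs follow the
    published operating point of the method.
    """

    canny_high_L: float = 30.0
    canny_low_L: float = 20.0
    canny_high_R: float = 20.0
    canny_low_R: float = 10.0
    canny_high_V: float = 300.0
    canny_low_V: float = 200.0
    min_len_F: int = 10
    min_len_V: int = 100
    gaussian_sigma: float = 1.0
    dilation_iterations: int = 2

    def __post_init__(self) -> None:
        for hi, lo in (
            (self.canny_high_L, self.canny_low_L),
            (self.canny_high_R, self.canny_low_R),
            (self.canny_high_V, self.canny_low_V),
        ):
            if not hi > lo > 0:
                raise ValueError("Canny thresholds must satisfy high > low > 0")
        if self.min_len_F < 0 or self.min_len_V < 0:
            raise ValueError("segment length cutoffs must be non-negative")

    def fluoro_thresholds(self, view: str) -> tuple[float, float]:
        if view == "L":
            return self.canny_high_L, self.canny_low_L
        if view == "R":
            return self.canny_high_R, self.canny_low_R
        raise ValueError(f"unknown view {view!r}")


@dataclass
class EdgeImage:
    """Binary or graded edge map.

    kind 'fluoro' and 'virtual' are {0,1}-valued; 'virtual_dilated' holds
    the graded ramp {0..iterations+1}.
    """

    pixels: np.ndarray
    kind: str = "fluoro"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.kind in ("fluoro", "virtual") and self.pixels.size:
            vals = np.unique(self.pixels)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{self.kind} edge image must be binary")

    @property
    def shape(self):
        return self.pixels.shape


# ---------------------------------------------------------------------------
# scalar operators
# ---------------------------------------------------------------------------

def gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing, reflect boundary; sigma 0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return img.copy()
    return ndi.gaussian_filter(img.astype(float), sigma, mode="reflect")


def canny_edges(img: np.ndarray, high: float, low: float) -> EdgeImage:
    """Binary Canny edge map (Sobel gradients, NMS, hysteresis)."""
    if not high > low > 0:
        raise ValueError("Canny thresholds must satisfy high > low > 0")
    e = feature.canny(
        img.astype(float), sigma=_CANNY_SIGMA, low_threshold=low, high_threshold=high
    )
    return EdgeImage(pixels=e.astype(np.uint8), kind="fluoro")


def filter_edge_segments(edges: EdgeImage, min_len: int) -> EdgeImage:
    """Keep 8-connected edge segments with pixel count > ``min_len``."""
    px = edges.pixels
    if not np.all(np.isin(np.unique(px), (0, 1))):
        raise ValueError("segment filtering expects a binary edge image")
    if min_len <= 0:
        return EdgeImage(px.copy(), kind=edges.kind)
    lab, n = measure.label(px, connectivity=2, return_num=True)
    if n == 0:
        return EdgeImage(px.copy(), kind=edges.kind)
    counts = np.bincount(lab.ravel())
    keep = counts > min_len
    keep[0] = False
    return EdgeImage(keep[lab].astype(np.uint8), kind=edges.kind)


def dilate_graded(edges: EdgeImage, iterations: int = 2) -> EdgeImage:
    """Graded dilation: sum of the mask and its successive 3x3 dilations.

    For ``iterations`` = 2 the result is a ramp with value 3 on the edge,
    2 at Chebyshev distance 1 and 1 at distance 2, giving the similarity
    an intensity gradient toward the true contour.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mask = edges.pixels.astype(bool)
    if not mask.any():
        return EdgeImage(np.zeros(mask.shape, np.uint8), kind="virtual_dilated")
    # ramp value at Chebyshev distance d from an edge pixel is
    # (iterations + 1 - d) for d <= iterations -- identical to summing the
    # mask with its successive 3x3 dilations, but in one distance transform
    d = ndi.distance_transform_cdt(~mask, metric="chessboard")
    out = np.clip(iterations + 1 - d, 0, None)
    return EdgeImage(out.astype(np.uint16), kind="virtual_dilated")


# ---------------------------------------------------------------------------
# silhouette rendering
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill_triangles(h, w, tris):  # pragma: no cover - compiled
    """Rasterize the union of 2D triangles onto an h x w grid.

    tris: (T, 3, 2) float array of (row, col) vertices; pixel centres at
    integer coordinates.
    """
    mask = np.zeros((h, w), np.uint8)
    for t in range(tris.shape[0]):
        r0, c0 = tris[t, 0, 0], tris[t, 0, 1]
        r1, c1 = tris[t, 1, 0], tris[t, 1, 1]
        r2, c2 = tris[t, 2, 0], tris[t, 2, 1]
        rmin = int(np.floor(min(r0, r1, r2)))
        rmax = int(np.ceil(max(r0, r1, r2)))
        cmin = int(np.floor(min(c0, c1, c2)))
        cmax = int(np.ceil(max(c0, c1, c2)))
        if rmax < 0 or cmax < 0 or rmin >= h or cmin >= w:
            continue
        rmin = max(rmin, 0)
        cmin = max(cmin, 0)
        rmax = min(rmax, h - 1)
        cmax = min(cmax, w - 1)
        area = (r1 - r0) * (c2 - c0) - (c1 - c0) * (r2 - r0)
        if area == 0.0:
            continue
        inv = 1.0 / area
        for r in range(rmin, rmax + 1):
            for c in range(cmin, cmax + 1):
                w0 = ((r1 - r) * (c2 - c) - (c1 - c) * (r2 - r)) * inv
                w1 = ((r2 - r) * (c0 - c) - (c2 - c) * (r0 - r)) * inv
                w2 = 1.0 - w0 - w1
                if w0 >= -1e-9 and w1 >= -1e-9 and w2 >= -1e-9:
                    mask[r, c] = 1
    return mask


def project_mesh_silhouette(
    model: ProjectionModel,
    mesh: BoneMesh,
    pose: Pose | None = None,
    shape: tuple[int, int] | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Binary silhouette of a posed mesh seen through ``model``.

    ``offset`` shifts pixel coordinates (for cropped rendering): output
    pixel (r, c) corresponds to detector pixel (r + offset[0], c + offset[1]).
    """
    posed = transform_mesh(mesh, pose) if pose is not None else mesh
    # frustum check: all vertices must be in front of the source
    w = np.hstack([posed.vertices, np.ones((len(posed.vertices), 1))]) @ model.P[2]
    if np.all(w <= 0):
        warnings.warn(f"mesh '{mesh.name}' entirely behind the source plane", stacklevel=2)
        h, wd = shape or (model.image_height, model.image_width)
        return np.zeros((h, wd), np.uint8)
    uv = project(model, posed.vertices)
    rc = uv[:, ::-1] - np.asarray(offset)  # (row, col)
    h, wd = shape or (model.image_height, model.image_width)
    tris = np.ascontiguousarray(rc[posed.faces], dtype=np.float64)
    return _fill_triangles(h, wd, tris)


def render_virtual_projection(
    model: ProjectionModel,
    meshes: list[BoneMesh],
    poses: list[Pose] | None = None,
    composite: bool = True,
    foreground: float = VIRTUAL_FOREGROUND,
):
    """Constant-intensity silhouette render of posed meshes through P.

    With ``composite`` the union (pixelwise max) of all bones is returned;
    otherwise one image per bone.  Intensities are on a 16-bit scale so
    that Canny at the virtual-image thresholds fires exactly on the
    occluding contours.
    """
    if not meshes:
        raise ValueError("no meshes to render")
    if poses is None:
        poses = [None] * len(meshes)
    imgs = [
        project_mesh_silhouette(model, m, p).astype(np.float64) * foreground
        for m, p in zip(meshes, poses)
    ]
    if composite:
        return np.maximum.reduce(imgs)
    return imgs


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------

def make_F(img: np.ndarray, params: EdgeParams, view: str) -> EdgeImage:
    """Edge-enhance a fluoroscopic image: smooth, Canny, length filter."""
    high, low = params.fluoro_thresholds(view)
    sm = gaussian_smooth(img, params.gaussian_sigma)
    e = canny_edges(sm, high, low)
    return filter_edge_segments(e, params.min_len_F)


def make_Vprime(
    render: np.ndarray, params: EdgeParams, dilation_iterations: int | None = None
) -> EdgeImage:
    """Edge-enhance and grade a virtual projection: Canny, filter, dilate.

    ``dilation_iterations`` overrides the configured ramp width (used by
    the optimiser's coarse search stages).
    """
    e = canny_edges(render, params.canny_high_V, params.canny_low_V)
    e.kind = "virtual"
    e = filter_edge_segments(e, params.min_len_V)
    it = params.dilation_iterations if dilation_iterations is None else dilation_iterations
    return dilate_graded(e, it)
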
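"""Point-to-mesh signed distances (numba).

Sign convention: positive inside the (closed) mesh, negative outside.
Distance is exact (closest point on any triangle); insideness is decided
by ray-crossing parity along +x with a tiny direction jitter to avoid
edge-on hits.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _closest_dist_sq(px, py, pz, tri):  # pragma: no cover - compiled
    """Squared distance from point p to one triangle (Ericson's method)."""
    ax, ay, az = tri[0, 0], tri[0, 1], tri[0, 2]
    bx, by, bz = tri[1, 0], tri[1, 1], tri[1, 2]
    cx, cy, cz = tri[2, 0], tri[2, 1], tri[2, 2]
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return apx * apx + apy * apy + apz * apz
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bpx * bpx + bpy * bpy + bpz * bpz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        qx, qy, qz = apx - v * abx, apy - v * aby, apz - v * abz
        return qx * qx + qy * qy + qz * qz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cpx * cpx + cpy * cpy + cpz * cpz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        qx, qy, qz = apx - w * acx, apy - w * acy, apz - w * acz
        return qx * qx + qy * qy + qz * qz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        qx = bpx - w * (cx - bx)
        qy = bpy - w * (cy - by)
        qz = bpz - w * (cz - bz)
        return qx * qx + qy * qy + qz * qz
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    qx = apx - v * abx - w * acx
    qy = apy - v * aby - w * acy
    qz = apz - v * abz - w * acz
    return qx * qx + qy * qy + qz * qz


@njit(cache=True)
def _signed_distance_impl(points, tris):  # pragma: no cover - compiled
    n = points.shape[0]
    out = np.empty(n)
    # slightly irrational ray direction avoids edge-on intersections
    dx, dy, dz = 1.0, 1e-4, 2e-4
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        best = 1e300
        crossings = 0
        for t in range(tris.shape[0]):
            d2 = _closest_dist_sq(px, py, pz, tris[t])
            if d2 < best:
                best = d2
            # Moller-Trumbore along (dx, dy, dz)
            e1x = tris[t, 1, 0] - tris[t, 0, 0]
            e1y = tris[t, 1, 1] - tris[t, 0, 1]
            e1z = tris[t, 1, 2] - tris[t, 0, 2]
            e2x = tris[t, 2, 0] - tris[t, 0, 0]
            e2y = tris[t, 2, 1] - tris[t, 0, 1]
            e2z = tris[t, 2, 2] - tris[t, 0, 2]
            hx = dy * e2z - dz * e2y
            hy = dz * e2x - dx * e2z
            hz = dx * e2y - dy * e2x
            a = e1x * hx + e1y * hy + e1z * hz
            if -1e-12 < a < 1e-12:
                continue
            f = 1.0 / a
            sx = px - tris[t, 0, 0]
            sy = py - tris[t, 0, 1]
            sz = pz - tris[t, 0, 2]
            u = f * (sx * hx + sy * hy + sz * hz)
            if u < 0.0 or u > 1.0:
                continue
            qx = sy * e1z - sz * e1y
            qy = sz * e1x - sx * e1z
            qz = sx * e1y - sy * e1x
            v = f * (dx * qx + dy * qy + dz * qz)
            if v < 0.0 or u + v > 1.0:
                continue
            tpar = f * (e2x * qx + e2y * qy + e2z * qz)
            if tpar > 0.0:
                crossings += 1
        d = np.sqrt(best)
        out[i] = d if (crossings % 2) == 1 else -d
    return out


def signed_distance(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed distance of points to a closed triangle mesh (positive inside)."""
    pts = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
    tris = np.ascontiguousarray(vertices[faces], dtype=np.float64)
    return _signed_distance_impl(pts, tris)
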
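"""Low-level geometric kernels shared by the orifice pipeline.

The heavy primitives — exact point-to-triangle-soup distance queries and
any-hit ray casting — are implemented as numba kernels over raw triangle
arrays.  Occluder meshes in this package are deliberately coarse (geometry
is piecewise flat, so a handful of large triangles represent it exactly),
which keeps a brute-force any-hit ray loop with early exit fast without a
BVH.  Distance queries are accelerated with a k-d tree over triangle
centroids plus a rigorous candidate-expansion bound, so results are exact,
not approximate.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

__all__ = [
    "TriangleField",
    "cone_directions",
    "triangle_areas",
    "triangle_centroids",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Areas of a triangle soup, shape (n_triangles,)."""
    a = vertices[triangles[:, 0]]
    e1 = vertices[triangles[:, 1]] - a
    e2 = vertices[triangles[:, 2]] - a
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def triangle_centroids(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    return vertices[triangles].mean(axis=1)


@njit(cache=True)
def _closest_point_on_triangle(p, a, b, c):
    """Closest point to ``p`` on triangle ``abc`` (Ericson, real-time CD)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab[0] * ap[0] + ab[1] * ap[1] + ab[2] * ap[2]
    d2 = ac[0] * ap[0] + ac[1] * ap[1] + ac[2] * ap[2]
    if d1 <= 0.0 and d2 <= 0.0:
        return a.copy()
    bp = p - b
    d3 = ab[0] * bp[0] + ab[1] * bp[1] + ab[2] * bp[2]
    d4 = ac[0] * bp[0] + ac[1] * bp[1] + ac[2] * bp[2]
    if d3 >= 0.0 and d4 <= d3:
        return b.copy()
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return a + v * ab
    cp = p - c
    d5 = ab[0] * cp[0] + ab[1] * cp[1] + ab[2] * cp[2]
    d6 = ac[0] * cp[0] + ac[1] * cp[1] + ac[2] * cp[2]
    if d6 >= 0.0 and d5 <= d6:
        return c.copy()
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return a + w * ac
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return a + v * ab + w * ac


@njit(cache=True)
def _closest_over_candidates(points, tri_a, tri_b, tri_c, cand, n_cand, out_pts, out_d):
    for i in range(points.shape[0]):
        p = points[i]
        best = np.inf
        for j in range(n_cand[i]):
            t = cand[i, j]
            q = _closest_point_on_triangle(p, tri_a[t], tri_b[t], tri_c[t])
            dx = p[0] - q[0]
            dy = p[1] - q[1]
            dz = p[2] - q[2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
                out_pts[i, 0] = q[0]
                out_pts[i, 1] = q[1]
                out_pts[i, 2] = q[2]
        out_d[i] = np.sqrt(best)


@njit(cache=True)
def _ray_hits_any(origin, direction, tmax, tri_a, tri_b, tri_c):
    """Möller–Trumbore any-hit against a triangle soup, early exit."""
    eps = 1e-12
    for t in range(tri_a.shape[0]):
        a = tri_a[t]
        e1x = tri_b[t, 0] - a[0]
        e1y = tri_b[t, 1] - a[1]
        e1z = tri_b[t, 2] - a[2]
        e2x = tri_c[t, 0] - a[0]
        e2y = tri_c[t, 1] - a[1]
        e2z = tri_c[t, 2] - a[2]
        px = direction[1] * e2z - direction[2] * e2y
        py = direction[2] * e2x - direction[0] * e2z
        pz = direction[0] * e2y - direction[1] * e2x
        det = e1x * px + e1y * py + e1z * pz
        if -eps < det < eps:
            continue
        inv = 1.0 / det
        sx = origin[0] - a[0]
        sy = origin[1] - a[1]
        sz = origin[2] - a[2]
        u = (sx * px + sy * py + sz * pz) * inv
        if u < 0.0 or u > 1.0:
            continue
        qx = sy * e1z - sz * e1y
        qy = sz * e1x - sx * e1z
        qz = sx * e1y - sy * e1x
        v = (direction[0] * qx + direction[1] * qy + direction[2] * qz) * inv
        if v < 0.0 or u + v > 1.0:
            continue
        thit = (e2x * qx + e2y * qy + e2z * qz) * inv
        if 1e-9 < thit < tmax:
            return True
    return False


@njit(cache=True)
def _rays_hit_any(origins, directions, tmax, tri_a, tri_b, tri_c, out):
    for i in range(origins.shape[0]):
        out[i] = _ray_hits_any(origins[i], directions[i], tmax, tri_a, tri_b, tri_c)


class TriangleField:
    """Exact distance / closest-point / ray-occlusion queries on a triangle soup.

    Candidate triangles for distance queries come from a k-d tree over
    centroids; the candidate set is provably sufficient whenever the best
    exact distance found is at most (distance to the k-th centroid) minus
    the largest triangle circumradius, and is expanded otherwise.
    """

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray):
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        triangles = np.ascontiguousarray(triangles, dtype=np.int64)
        if len(triangles) == 0:
            raise ValueError("TriangleField requires at least one triangle")
        self.tri_a = np.ascontiguousarray(vertices[triangles[:, 0]])
        self.tri_b = np.ascontiguousarray(vertices[triangles[:, 1]])
        self.tri_c = np.ascontiguousarray(vertices[triangles[:, 2]])
        self.centroids = (self.tri_a + self.tri_b + self.tri_c) / 3.0
        # radius of the smallest centroid-centred ball containing each triangle
        r = np.maximum(
            np.linalg.norm(self.tri_a - self.centroids, axis=1),
            np.maximum(
                np.linalg.norm(self.tri_b - self.centroids, axis=1),
                np.linalg.norm(self.tri_c - self.centroids, axis=1),
            ),
        )
        self.max_radius = float(r.max())
        self.n_triangles = len(triangles)
        self._tree = cKDTree(self.centroids)

    def closest(self, points: np.ndarray, k: int = 16):
        """Return (distances, closest_points) for each query point. Exact."""
        points = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
        n = points.shape[0]
        k = min(k, self.n_triangles)
        d_cent, idx = self._tree.query(points, k=k)
        if k == 1:
            d_cent = d_cent[:, None]
            idx = idx[:, None]
        cand = np.ascontiguousarray(idx, dtype=np.int64)
        n_cand = np.full(n, k, dtype=np.int64)
        out_pts = np.empty((n, 3))
        out_d = np.empty(n)
        _closest_over_candidates(
            points, self.tri_a, self.tri_b, self.tri_c, cand, n_cand, out_pts, out_d
        )
        if k < self.n_triangles:
            # a triangle not in the candidate set could still be closer if its
            # centroid lies within best_d + max_radius of the query point
            unsafe = out_d + self.max_radius > d_cent[:, -1]
            if np.any(unsafe):
                sub = np.where(unsafe)[0]
                balls = self._tree.query_ball_point(
                    points[sub], out_d[sub] + self.max_radius + 1e-12
                )
                m = max((len(b) for b in balls), default=1)
                cand2 = np.zeros((len(sub), max(m, 1)), dtype=np.int64)
                n2 = np.zeros(len(sub), dtype=np.int64)
                for i, b in enumerate(balls):
                    n2[i] = len(b)
                    cand2[i, : len(b)] = b
                pts2 = np.empty((len(sub), 3))
                d2 = np.empty(len(sub))
                _closest_over_candidates(
                    np.ascontiguousarray(points[sub]),
                    self.tri_a, self.tri_b, self.tri_c, cand2, n2, pts2, d2,
                )
                better = d2 < out_d[sub]
                out_d[sub[better]] = d2[better]
                out_pts[sub[better]] = pts2[better]
        return out_d, out_pts

    def distance(self, points: np.ndarray) -> np.ndarray:
        return self.closest(points)[0]

    def rays_hit(self, origins: np.ndarray, directions: np.ndarray, tmax: float) -> np.ndarray:
        """Boolean per ray: does the ray hit any triangle within ``tmax``."""
        origins = np.ascontiguousarray(np.atleast_2d(origins), dtype=np.float64)
        directions = np.ascontiguousarray(np.atleast_2d(directions), dtype=np.float64)
        out = np.zeros(origins.shape[0], dtype=np.bool_)
        _rays_hit_any(origins, directions, float(tmax), self.tri_a, self.tri_b, self.tri_c, out)
        return out


def cone_directions(n: int, axis: np.ndarray, half_angle_deg: float) -> np.ndarray:
    """Deterministic quasi-uniform unit directions inside a cone.

    Golden-angle (Fibonacci-spiral) azimuths combined with a base-2 radical
    inverse for the polar coordinate.  The sequence is *nested*: the first m
    directions of an n-direction set equal the m-direction set, which makes
    any escape-based classification monotone in the ray count.  Direction 0
    is exactly the cone axis.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    k = np.arange(n)
    # van der Corput radical inverse in base 2 (u[0] = 0 -> axis direction)
    u = np.zeros(n)
    denom = 2.0
    kk = k.copy()
    while kk.any():
        u += (kk % 2) / denom
        kk //= 2
        denom *= 2.0
    cos_a = np.cos(np.radians(half_angle_deg))
    cos_t = 1.0 - (1.0 - cos_a) * u  # uniform in solid angle within the cone
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    phi = k * _GOLDEN_ANGLE
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    # orthonormal frame with +z along the cone axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    frame = np.column_stack([e1, e2, axis])
    return local @ frame.T
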
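"""Synthetic valve-like geometry with analytically known orifice areas.

Real closed-valve meshes come from patient-specific finite element
simulations; for development and verification this module generates
occluder geometries whose regurgitant orifice areas are known exactly by
construction:

* ``plate_hole`` / ``plate_multi_hole`` — a flat circular plate with one or
  more circular through-holes (orifice area = sum of pi r^2); hole rims are
  meshed with boundary-conforming vertex rings so the analytic area is an
  honest oracle at moderate resolution.
* ``intact_plate`` — a plate with no hole (zero orifice).
* ``crease_trap`` — a plate with two deep, narrow, *sealed* trenches that
  the cover surface bridges (inflating the potential orifice area) plus one
  genuine through-slot continued by a deep collimating shaft; only the slot
  is a true orifice.  This is the stress test for the ray-cast filter.
* ``dome_hole`` — a spherical cap with a polar hole (approximate truth:
  the chord-plane disk area).
* ``coapted_leaflets`` — two inclined leaflets meeting along a coaptation
  ridge with a central gap (approximate truth: the projected gap area).

All fixtures are deterministic functions of their specification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .mesh_io import LandmarkSet, SurfaceMesh

__all__ = ["FixtureSpec", "FixtureTruth", "Fixture", "make_fixture", "make_traction_fixture"]

KINDS = ("plate_hole", "plate_multi_hole", "crease_trap", "dome_hole",
         "coapted_leaflets", "intact_plate")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic test geometry (lengths in mm)."""

    kind: str = "plate_hole"
    plate_radius: float = 20.0
    hole_radii: tuple = (5.0,)
    hole_centers: tuple = ((0.0, 0.0),)
    edge_length: float | None = None  # None -> min hole radius / 20
    thickness: float = 0.396
    ring_radius: float = 12.0  # landmark ring around the orifice region
    n_landmarks: int = 12
    # crease-trap parameters
    trench_size: tuple = (3.0, 20.0)  # width x length of each sealed trench
    trench_offset: float = 8.0  # trench centerline distance from the slot
    trench_depth: float = 10.0
    slot_size: tuple = (2.0, 10.0)  # width x length of the true through-slot
    shaft_depth: float = 60.0
    # dome parameters
    dome_radius: float = 15.0
    dome_hole_angle: float = 20.0  # polar half-angle of the hole, degrees
    # coapted-leaflet parameters
    leaflet_span: float = 12.0  # annulus-to-ridge extent of each leaflet
    gap: tuple = (3.0, 10.0)  # gap width x length along the coaptation line
    coaptation_drop: float = 6.0  # ridge depth below the annulus plane
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.kind in ("plate_hole", "plate_multi_hole"):
            for (cx, cy), r in zip(self.hole_centers, self.hole_radii):
                if np.hypot(cx, cy) + r >= self.plate_radius:
                    raise ValueError("holes must lie strictly inside the plate")
                if np.hypot(cx, cy) + r >= self.ring_radius:
                    raise ValueError("landmark ring must enclose every hole")
        if self.kind == "crease_trap":
            if self.slot_size[0] * self.slot_size[1] >= \
                    2 * self.trench_size[0] * self.trench_size[1]:
                raise ValueError("slot area must be smaller than the trench footprint")

    @property
    def edge(self) -> float:
        if self.edge_length is not None:
            return self.edge_length
        if self.kind in ("plate_hole", "plate_multi_hole"):
            return min(self.hole_radii) / 20.0
        return 0.5


@dataclass(frozen=True)
class FixtureTruth:
    """Exact (or construction-level approximate) reference quantities."""

    roa: float  # mm^2
    n_components: int
    trap_area: float = 0.0  # bridged-but-sealed footprint, mm^2
    hole_polygon_area: float | None = None  # area actually enclosed by the meshed rims
    approximate: bool = False


@dataclass(frozen=True)
class Fixture:
    mesh: SurfaceMesh  # leaflet midsurface (or, thickness 0, the occluder itself)
    landmarks: LandmarkSet
    truth: FixtureTruth
    thickness: float  # inflation thickness to use with this fixture


def _ring_landmarks(radius: float, z: float, n: int) -> LandmarkSet:
    theta = 2 * np.pi * np.arange(n) / n
    return LandmarkSet(np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(n, z)]))


# ---------------------------------------------------------------------------
# plates with circular holes (2D Delaunay with rim-conforming rings)

def _plate_with_holes(spec: FixtureSpec) -> tuple[SurfaceMesh, float]:
    edge = spec.edge
    holes = list(zip(spec.hole_centers, spec.hole_radii))
    pts = []
    poly_area = 0.0
    for (cx, cy), r in holes:
        n = max(24, int(round(2 * np.pi * r / edge)))
        th = 2 * np.pi * np.arange(n) / n
        pts.append(np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]))
        poly_area += 0.5 * n * r * r * np.sin(2 * np.pi / n)
    n_out = max(48, int(round(2 * np.pi * spec.plate_radius / max(4 * edge, edge))))
    th = 2 * np.pi * np.arange(n_out) / n_out
    pts.append(spec.plate_radius * np.column_stack([np.cos(th), np.sin(th)]))
    # light interior grid keeps triangle shapes reasonable; geometry is planar
    # so coarse interior triangles are still exact
    h = max(3.0 * edge, spec.plate_radius / 24.0)
    xs = np.arange(-spec.plate_radius, spec.plate_radius + h, h)
    gx, gy = np.meshgrid(xs, xs * np.sqrt(3) / 2)
    gx[1::2] += h / 2
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    keep = np.hypot(grid[:, 0], grid[:, 1]) < spec.plate_radius - 0.7 * h
    for (cx, cy), r in holes:
        keep &= np.hypot(grid[:, 0] - cx, grid[:, 1] - cy) > r + 0.7 * h
    pts.append(grid[keep])
    p2 = np.vstack(pts)
    tri = Delaunay(p2)
    simplices = tri.simplices
    cent = p2[simplices].mean(axis=1)
    ok = np.ones(len(simplices), dtype=bool)
    for (cx, cy), r in holes:
        ok &= np.hypot(cent[:, 0] - cx, cent[:, 1] - cy) > r
    simplices = simplices[ok]
    # enforce counter-clockwise winding (+z normals)
    a = p2[simplices[:, 0]]
    cross = ((p2[simplices[:, 1]] - a)[:, 0] * (p2[simplices[:, 2]] - a)[:, 1]
             - (p2[simplices[:, 1]] - a)[:, 1] * (p2[simplices[:, 2]] - a)[:, 0])
    flip = cross < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]
    verts = np.column_stack([p2, np.zeros(len(p2))])
    return SurfaceMesh(verts, [tuple(t) for t in simplices]).clean(), poly_area


def _plate_fixture(spec: FixtureSpec) -> Fixture:
    mesh, poly_area = _plate_with_holes(spec)
    lm = _ring_landmarks(spec.ring_radius, spec.thickness / 2.0, spec.n_landmarks)
    roa = float(sum(np.pi * r * r for r in spec.hole_radii))
    truth = FixtureTruth(roa=roa, n_components=len(spec.hole_radii),
                         hole_polygon_area=poly_area)
    return Fixture(mesh=mesh, landmarks=lm, truth=truth, thickness=spec.thickness)


def _intact_plate_fixture(spec: FixtureSpec) -> Fixture:
    flat = FixtureSpec(kind="plate_hole", plate_radius=spec.plate_radius,
                       hole_radii=(), hole_centers=(),
                       edge_length=spec.edge_length or 0.5,
                       thickness=spec.thickness, ring_radius=spec.ring_radius,
                       n_landmarks=spec.n_landmarks)
    mesh, _ = _plate_with_holes(flat)
    lm = _ring_landmarks(spec.ring_radius, spec.thickness / 2.0, spec.n_landmarks)
    return Fixture(mesh=mesh, landmarks=lm,
                   truth=FixtureTruth(roa=0.0, n_components=0),
                   thickness=spec.thickness)


# ---------------------------------------------------------------------------
# crease trap

def _quads_mesh(quads: list) -> SurfaceMesh:
    """Mesh from a list of 4-corner rectangles (each split into 2 triangles)."""
    verts, faces = [], []
    for q in quads:
        base = len(verts)
        verts.extend(q)
        faces.append((base, base + 1, base + 2))
        faces.append((base, base + 2, base + 3))
    return SurfaceMesh(np.asarray(verts, dtype=np.float64), faces).clean(merge_tol=1e-9)


def _cover_rects(x0, x1, y0, y1, openings):
    """Axis-aligned rectangle decomposition of [x0,x1]x[y0,y1] minus openings."""
    xs = sorted({x0, x1, *(o[0] for o in openings), *(o[1] for o in openings)})
    rects = []
    for xa, xb in zip(xs[:-1], xs[1:]):
        if xb <= x0 or xa >= x1 or xb - xa <= 0:
            continue
        xm = 0.5 * (xa + xb)
        cuts = sorted({y0, y1} | {v for ox0, ox1, oy0, oy1 in openings
                                  if ox0 <= xm <= ox1 for v in (oy0, oy1)})
        for ya, yb in zip(cuts[:-1], cuts[1:]):
            ym = 0.5 * (ya + yb)
            inside_open = any(ox0 <= xm <= ox1 and oy0 <= ym <= oy1
                              for ox0, ox1, oy0, oy1 in openings)
            if not inside_open and yb > ya:
                rects.append((max(xa, x0), min(xb, x1), ya, yb))
    return rects


def _box_walls(x0, x1, y0, y1, z_top, z_bot, with_bottom: bool) -> list:
    quads = [
        [(x0, y0, z_top), (x0, y0, z_bot), (x0, y1, z_bot), (x0, y1, z_top)],
        [(x1, y0, z_top), (x1, y1, z_top), (x1, y1, z_bot), (x1, y0, z_bot)],
        [(x0, y0, z_top), (x1, y0, z_top), (x1, y0, z_bot), (x0, y0, z_bot)],
        [(x0, y1, z_top), (x0, y1, z_bot), (x1, y1, z_bot), (x1, y1, z_top)],
    ]
    if with_bottom:
        quads.append([(x0, y0, z_bot), (x1, y0, z_bot), (x1, y1, z_bot), (x0, y1, z_bot)])
    return quads


def _crease_trap_fixture(spec: FixtureSpec) -> Fixture:
    tw, tl = spec.trench_size
    sw, sl = spec.slot_size
    off = spec.trench_offset
    openings = [
        (-off - tw / 2, -off + tw / 2, -tl / 2, tl / 2),  # left trench
        (off - tw / 2, off + tw / 2, -tl / 2, tl / 2),  # right trench
        (-sw / 2, sw / 2, -sl / 2, sl / 2),  # through-slot
    ]
    px = off + tw / 2 + 10.0
    py = tl / 2 + 6.0
    quads = []
    for xa, xb, ya, yb in _cover_rects(-px, px, -py, py, openings):
        quads.append([(xa, ya, 0.0), (xb, ya, 0.0), (xb, yb, 0.0), (xa, yb, 0.0)])
    for ox0, ox1, oy0, oy1 in openings[:2]:
        quads += _box_walls(ox0, ox1, oy0, oy1, 0.0, -spec.trench_depth, with_bottom=True)
    quads += _box_walls(-sw / 2, sw / 2, -sl / 2, sl / 2, 0.0,
                        -spec.shaft_depth, with_bottom=False)
    mesh = _quads_mesh(quads)
    r_ring = np.hypot(off + tw / 2, tl / 2) + 0.5  # just outside the trench corners
    lm = _ring_landmarks(r_ring, 0.0, spec.n_landmarks)
    truth = FixtureTruth(roa=sw * sl, n_components=1, trap_area=2 * tw * tl)
    return Fixture(mesh=mesh, landmarks=lm, truth=truth, thickness=0.0)


# ---------------------------------------------------------------------------
# dome with a polar hole, coapted leaflets (approximate truths)

def _stitch_rings(inner, outer):
    from .orifice import _stitch_rings as stitch

    return stitch(inner, outer)


def _dome_fixture(spec: FixtureSpec) -> Fixture:
    R = spec.dome_radius
    a = np.radians(spec.dome_hole_angle)
    theta_max = np.radians(75.0)
    n_lat = 24
    thetas = np.linspace(a, theta_max, n_lat)
    verts, rings = [], []
    for th in thetas:
        n_k = max(24, int(round(2 * np.pi * R * np.sin(th) / (R * (theta_max - a) / n_lat))))
        phi = 2 * np.pi * np.arange(n_k) / n_k
        start = len(verts)
        verts.extend(np.column_stack([
            R * np.sin(th) * np.cos(phi), R * np.sin(th) * np.sin(phi),
            np.full(n_k, R * np.cos(th)),
        ]))
        rings.append(list(range(start, start + n_k)))
    faces = []
    for inner, outer in zip(rings[:-1], rings[1:]):
        faces.extend(_stitch_rings(inner, outer))
    mesh = SurfaceMesh(np.asarray(verts), faces).clean()
    lm_theta = min(theta_max - 0.1, a + np.radians(25.0))
    lm = LandmarkSet(np.column_stack([
        R * np.sin(lm_theta) * np.cos(2 * np.pi * np.arange(spec.n_landmarks) / spec.n_landmarks),
        R * np.sin(lm_theta) * np.sin(2 * np.pi * np.arange(spec.n_landmarks) / spec.n_landmarks),
        np.full(spec.n_landmarks, R * np.cos(lm_theta)),
    ]))
    truth = FixtureTruth(roa=float(np.pi * (R * np.sin(a)) ** 2), n_components=1,
                         approximate=True)
    return Fixture(mesh=mesh, landmarks=lm, truth=truth, thickness=spec.thickness)


def _coapted_fixture(spec: FixtureSpec) -> Fixture:
    gw, gl = spec.gap
    W = spec.leaflet_span
    L = gl + 2 * W  # leaflet length along the coaptation line
    drop = spec.coaptation_drop
    h = 0.6
    quads = []
    for side in (+1, -1):
        # leaflet in the plane z = drop*(|y|/W - 1); notched near the ridge
        openings = [(-gl / 2, gl / 2, 0.0, gw / 2)] if gw > 0 else []
        for xa, xb, ya, yb in _cover_rects(-L / 2, L / 2, 0.0, W, openings):
            nx = max(1, int(round((xb - xa) / h)))
            ny = max(1, int(round((yb - ya) / h)))
            for i in range(nx):
                for j in range(ny):
                    x0 = xa + (xb - xa) * i / nx
                    x1 = xa + (xb - xa) * (i + 1) / nx
                    y0 = ya + (yb - ya) * j / ny
                    y1 = ya + (yb - ya) * (j + 1) / ny
                    z0 = drop * (y0 / W - 1.0)
                    z1 = drop * (y1 / W - 1.0)
                    quads.append([
                        (x0, side * y0, z0), (x1, side * y0, z0),
                        (x1, side * y1, z1), (x0, side * y1, z1),
                    ])
    mesh = _quads_mesh(quads)
    n = spec.n_landmarks
    th = 2 * np.pi * np.arange(n) / n
    rx, ry = gl / 2 + 4.0, gw / 2 + 3.0
    pts = np.column_stack([rx * np.cos(th), ry * np.sin(th)])
    z = drop * (np.abs(pts[:, 1]) / W - 1.0)
    lm = LandmarkSet(np.column_stack([pts, z]))
    truth = FixtureTruth(roa=gw * gl, n_components=1, approximate=True)
    return Fixture(mesh=mesh, landmarks=lm, truth=truth, thickness=spec.thickness)


# ---------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the occluder mesh, landmark ring and analytic truth for a spec."""
    if spec.kind in ("plate_hole", "plate_multi_hole"):
        return _plate_fixture(spec)
    if spec.kind == "intact_plate":
        return _intact_plate_fixture(spec)
    if spec.kind == "crease_trap":
        return _crease_trap_fixture(spec)
    if spec.kind == "dome_hole":
        return _dome_fixture(spec)
    if spec.kind == "coapted_leaflets":
        return _coapted_fixture(spec)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def make_traction_fixture(side: float = 10.0, edge: float = 0.5,
                          contact_fraction: float = 0.5,
                          field_name: str = "traction") -> tuple[SurfaceMesh, float]:
    """Square plate with a contiguous positive-traction region.

    Faces are swept in x until the requested fraction of the total area is
    accumulated; returns (mesh, true contact area in mm^2).
    """
    if not 0.0 <= contact_fraction <= 1.0:
        raise ValueError("contact_fraction must be in [0, 1]")
    n = max(1, int(round(side / edge)))
    xs = np.linspace(-side / 2, side / 2, n + 1)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            faces.append((a, a + n + 1, a + n + 2, a + 1))
    mesh = SurfaceMesh(verts, faces)
    areas = mesh.face_areas()
    order = np.lexsort((mesh.face_centroids()[:, 1], mesh.face_centroids()[:, 0]))
    target = contact_fraction * areas.sum()
    csum = np.cumsum(areas[order])
    n_on = int(np.searchsorted(csum, target, side="left"))
    if n_on < len(order) and contact_fraction > 0 and \
            abs(csum[n_on] - target) <= abs((csum[n_on - 1] if n_on else 0.0) - target):
        n_on += 1
    traction = np.zeros(mesh.n_faces)
    traction[order[:n_on]] = 1.0
    mesh.cell_fields[field_name] = traction
    true_area = float(areas[order[:n_on]].sum())
    return mesh, true_area
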
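"""Regurgitant orifice area (ROA) from a closed-valve surface mesh.

The pipeline quantifies the leak area of an incompletely closed valve at
systole without any view-angle dependence:

1. inflate the leaflet midsurface mesh by the physical leaflet thickness to
   obtain a closed occluder;
2. fit a closed periodic spline contour through user landmarks placed near
   the orifice;
3. warp a flat disk template onto the contour (harmonic interpolation of
   the boundary) to get a continuous cover surface;
4. shrink-wrap: iteratively Laplacian-smooth, redistribute, and displace
   the cover down the unsigned-distance gradient of the occluder until the
   potential-orifice area stops changing;
5. classify cover patches as contact vs potential orifice by distance to
   the occluder;
6. filter the potential patches by casting a deterministic fan of rays in
   a cone about each patch's through-flow normal: a patch is a confirmed
   (valid) orifice patch only if at least one ray escapes the occluder;
7. sum valid patch areas, grouping edge-connected patches into individual
   orifices (multiple regurgitant jets are reported separately).

The ray filter is what distinguishes a true through-flow channel from a
pocket: a cover that bridges a deep sealed crease has large potential area
but no escaping rays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import CubicSpline
from scipy.sparse.csgraph import connected_components

from .geometry import TriangleField, cone_directions, triangle_areas
from .mesh_io import ContentError, LandmarkSet, SurfaceMesh

log = logging.getLogger(__name__)

__all__ = [
    "RoaConfig",
    "OrificeContour",
    "WrapSurface",
    "OrificeResult",
    "LABELS",
    "inflate_surface",
    "build_contour",
    "warp_disk_to_contour",
    "classify_patches",
    "shrink_wrap",
    "raycast_filter",
    "compute_roa",
]

# per-face patch labels
CONTACT, POTENTIAL, VALID, INVALID = 0, 1, 2, 3
LABELS = {CONTACT: "contact", POTENTIAL: "potential_orifice",
          VALID: "valid_orifice", INVALID: "invalid_orifice"}


@dataclass(frozen=True)
class RoaConfig:
    """Tunable parameters of the ROA pipeline (lengths in mm)."""

    thickness: float = 0.396  # leaflet thickness used for inflation
    n_rays: int = 400  # rays per potential patch
    cone_angle: float = 50.0  # full apex angle of the ray cone, degrees
    area_tol: float = 1e-3  # relative potential-area change to stop iterating
    max_iters: int = 100
    remesh_vertices: int = 4000  # target vertex count of the cover surface
    ray_max_length: float | None = None  # None -> 4x occluder bbox diagonal
    smooth_iters_per_cycle: int = 5
    contact_dist: float | None = None  # None -> 5% of mean cover edge length
    step_factor: float = 0.5  # displacement cap, fraction of mean edge length
    escape_validates: bool = True  # one escaping ray validates a patch
    flip_normal: bool = False  # flip the inferred through-flow direction

    def __post_init__(self):
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")
        if not 0.0 < self.cone_angle < 180.0:
            raise ValueError("cone_angle must be in (0, 180) degrees")
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if self.max_iters < 1 or self.remesh_vertices < 10:
            raise ValueError("max_iters >= 1 and remesh_vertices >= 10 required")


@dataclass(frozen=True)
class OrificeContour:
    control_points: LandmarkSet
    resampled_curve: np.ndarray  # (n, 3), closed (last point adjacent to first)


@dataclass
class WrapSurface:
    """The evolving cover surface with per-face patch labels."""

    mesh: SurfaceMesh
    patch_label: np.ndarray  # int per face, see LABELS
    boundary_vertices: np.ndarray  # bool per vertex, pinned during smoothing
    iteration: int = 0
    converged: bool = True
    area_history: list = field(default_factory=list)

    def face_areas(self) -> np.ndarray:
        return self.mesh.face_areas()

    def area_of(self, label: int) -> float:
        return float(self.face_areas()[self.patch_label == label].sum())

    @property
    def potential_area(self) -> float:
        return self.area_of(POTENTIAL) + self.area_of(VALID) + self.area_of(INVALID)

    def labeled_mesh(self) -> SurfaceMesh:
        """Copy of the cover mesh carrying the labels as a cell field."""
        out = self.mesh.copy()
        out.cell_fields["patch_label"] = self.patch_label.astype(np.float64)
        return out


@dataclass(frozen=True)
class OrificeResult:
    roa: float  # mm^2, sum of valid orifice patches
    components: list  # per connected orifice: {"face_ids", "area_mm2", "n_faces"}
    potential_area: float  # mm^2 before ray filtering
    wrap_area: float  # mm^2, whole cover surface
    converged: bool
    iterations: int
    config_echo: RoaConfig
    wrap: WrapSurface


# ---------------------------------------------------------------------------
# stage 1: inflation

def inflate_surface(leaflet: SurfaceMesh, thickness: float) -> SurfaceMesh:
    """Thicken a midsurface mesh into a closed occluder shell.

    Each vertex is offset +/- thickness/2 along its area-weighted normal
    (FE shells are midsurface representations, so half the physical
    thickness lies on each side); open boundaries are closed with side
    walls so the result is watertight wherever the input permits.
    """
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    if thickness == 0.0:
        return leaflet.copy()
    tm = leaflet.as_trimesh()
    normals = np.asarray(tm.vertex_normals, dtype=np.float64)
    n_v = leaflet.n_vertices
    half = 0.5 * thickness
    top = leaflet.vertices + half * normals
    bottom = leaflet.vertices - half * normals
    verts = np.vstack([top, bottom])
    tris = leaflet.triangles
    faces = [tuple(t) for t in tris]  # top shell, original winding
    faces += [(int(t[0]) + n_v, int(t[2]) + n_v, int(t[1]) + n_v) for t in tris]  # bottom, flipped
    # close open boundaries: edges used by exactly one triangle, in face order
    edge_count: dict = {}
    for t in tris:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            edge_count[(int(a), int(b))] = edge_count.get((int(a), int(b)), 0) + 1
    for (a, b), cnt in edge_count.items():
        if cnt == 1 and (b, a) not in edge_count:
            # wall quad oriented outward for a consistently wound input
            faces.append((b + n_v, a + n_v, a, b))
    return SurfaceMesh(verts, faces).clean(merge_tol=1e-12)


# ---------------------------------------------------------------------------
# stage 2: contour

def _best_fit_plane(points: np.ndarray):
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center, full_matrices=False)
    return center, vt[0], vt[1], vt[2]  # origin, in-plane axes, normal


def _projected_polygon_area(points: np.ndarray) -> float:
    center, e1, e2, _ = _best_fit_plane(points)
    x = (points - center) @ e1
    y = (points - center) @ e2
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def build_contour(landmarks: LandmarkSet, n_samples: int = 200) -> OrificeContour:
    """Closed periodic cubic spline through the landmarks, resampled to
    approximately equal arc length."""
    pts = landmarks.points
    if len(pts) < 3:
        raise ContentError("need at least 3 landmarks for a closed contour")
    closed = np.vstack([pts, pts[:1]])
    chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(chord == 0):
        raise ContentError("consecutive duplicate landmark points")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, closed, bc_type="periodic")
    dense = spline(np.linspace(0.0, t[-1], 40 * n_samples + 1))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n_samples, endpoint=False)
    idx = np.searchsorted(arc, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - arc[idx]) / np.maximum(seg[idx], 1e-300)
    curve = dense[idx] + frac[:, None] * (dense[idx + 1] - dense[idx])

    area = _projected_polygon_area(curve)
    perimeter = float(arc[-1])
    if area < 1e-9 * perimeter**2:
        raise ContentError(
            "degenerate contour: landmarks enclose no area in their best-fit plane")
    import shapely.geometry as sg

    center, e1, e2, _ = _best_fit_plane(curve)
    ring = sg.Polygon(np.column_stack([(curve - center) @ e1, (curve - center) @ e2]))
    if not ring.is_valid:
        raise ContentError("contour is self-intersecting in its best-fit plane")
    return OrificeContour(control_points=landmarks, resampled_curve=curve)


# ---------------------------------------------------------------------------
# stage 3: disk template warped to the contour

def _disk_template(n_boundary: int, target_vertices: int):
    """Flat unit-disk triangulation: center + concentric rings, the outermost
    ring having exactly ``n_boundary`` vertices.  Returns (vertices-2d, faces,
    boundary vertex ids ordered by angle)."""
    n_rings = max(2, round(2.0 * target_vertices / n_boundary))
    verts = [(0.0, 0.0)]
    rings = []
    for k in range(1, n_rings + 1):
        r = k / n_rings
        n_k = n_boundary if k == n_rings else max(6, round(n_boundary * k / n_rings))
        theta = 2.0 * np.pi * np.arange(n_k) / n_k
        start = len(verts)
        verts.extend(zip(r * np.cos(theta), r * np.sin(theta)))
        rings.append(list(range(start, start + n_k)))
    faces = [(0, rings[0][j], rings[0][(j + 1) % len(rings[0])]) for j in range(len(rings[0]))]
    for inner, outer in zip(rings[:-1], rings[1:]):
        faces.extend(_stitch_rings(inner, outer))
    return np.asarray(verts), faces, rings[-1]


def _stitch_rings(inner: list, outer: list) -> list:
    """Triangulate the closed band between two concentric vertex rings."""
    n_in, n_out = len(inner), len(outer)
    faces, i, j = [], 0, 0
    while i < n_in or j < n_out:
        adv_inner = j >= n_out or (i < n_in and (i + 1) * n_out <= (j + 1) * n_in)
        if adv_inner:
            faces.append((inner[i % n_in], outer[j % n_out], inner[(i + 1) % n_in]))
            i += 1
        else:
            faces.append((inner[i % n_in], outer[j % n_out], outer[(j + 1) % n_out]))
            j += 1
    return faces


def warp_disk_to_contour(contour: OrificeContour, remesh_vertices: int = 4000) -> WrapSurface:
    """Map a flat disk template onto the contour; interior positions are the
    harmonic (graph-Laplacian) interpolation of the boundary, so the cover is
    smooth and exactly interpolates the resampled contour."""
    curve = contour.resampled_curve
    n_b = len(curve)
    verts2d, faces, boundary = _disk_template(n_b, remesh_vertices)
    n = len(verts2d)
    boundary_mask = np.zeros(n, dtype=bool)
    boundary_mask[boundary] = True

    rows, cols = [], []
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            rows += [a, b]
            cols += [b, a]
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0  # duplicate edges collapse to simple adjacency
    adj.sum_duplicates()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()

    interior = ~boundary_mask
    verts = np.zeros((n, 3))
    verts[boundary] = curve  # template boundary vertex j <-> contour sample j
    lap = sp.diags(deg[interior]) - adj[interior][:, interior]
    rhs = adj[interior][:, boundary_mask] @ verts[boundary_mask]
    verts[interior] = sp.linalg.spsolve(lap.tocsc(), rhs)

    mesh = SurfaceMesh(verts, faces)
    return WrapSurface(
        mesh=mesh,
        patch_label=np.full(mesh.n_faces, POTENTIAL, dtype=np.int64),
        boundary_vertices=boundary_mask,
    )


# ---------------------------------------------------------------------------
# stages 4-6: classification, shrink-wrap, ray filtering

def _as_field(occluder) -> TriangleField:
    if isinstance(occluder, TriangleField):
        return occluder
    return TriangleField(occluder.vertices, occluder.triangles)


def _mean_edge_length(mesh: SurfaceMesh) -> float:
    tris = mesh.triangles
    v = mesh.vertices
    e = np.concatenate([
        np.linalg.norm(v[tris[:, 0]] - v[tris[:, 1]], axis=1),
        np.linalg.norm(v[tris[:, 1]] - v[tris[:, 2]], axis=1),
        np.linalg.norm(v[tris[:, 2]] - v[tris[:, 0]], axis=1),
    ])
    return float(e.mean())


def default_contact_dist(wrap: WrapSurface, config: RoaConfig) -> float:
    """Default contact threshold: 5% of the mean cover edge length.

    The shrink-wrap snaps contact vertices onto the occluder surface, so the
    residual distance in true contact regions is essentially zero; a small
    threshold keeps the misclassified rim band around each orifice thin.
    """
    if config.contact_dist is not None:
        return config.contact_dist
    return 0.05 * _mean_edge_length(wrap.mesh)


def classify_patches(wrap: WrapSurface, occluder, contact_dist: float) -> WrapSurface:
    """Label each cover face contact / potential by centroid distance to the
    occluder.  Valid/invalid labels (from a previous ray pass) are reset."""
    fld = _as_field(occluder)
    centroids = wrap.mesh.face_centroids()
    d = fld.distance(centroids)
    wrap.patch_label = np.where(d <= contact_dist, CONTACT, POTENTIAL).astype(np.int64)
    return wrap


def shrink_wrap(wrap: WrapSurface, occluder, config: RoaConfig) -> WrapSurface:
    """Iteratively smooth, redistribute and displace the cover toward the
    occluder until the potential-orifice area stops changing.

    Each cycle applies boundary-pinned uniform Laplacian smoothing (which
    both regularizes the surface and redistributes vertices isotropically —
    connectivity is kept fixed), then moves every free vertex toward its
    closest occluder point along the negative unsigned-distance gradient,
    with the step capped at ``step_factor`` x mean edge length to prevent
    tunnelling, and finally reclassifies the patches.
    """
    fld = _as_field(occluder)
    mesh = wrap.mesh
    n = mesh.n_vertices
    free = ~wrap.boundary_vertices

    rows, cols = [], []
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            rows += [a, b]
            cols += [b, a]
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    adj.sum_duplicates()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv_deg = 1.0 / np.maximum(deg, 1)

    mean_edge = _mean_edge_length(mesh)
    cap = config.step_factor * mean_edge
    contact_dist = default_contact_dist(wrap, config)

    verts = mesh.vertices
    classify_patches(wrap, fld, contact_dist)
    wrap.area_history = [wrap.potential_area]
    wrap.converged = False
    for it in range(1, config.max_iters + 1):
        for _ in range(config.smooth_iters_per_cycle):
            avg = (adj @ verts) * inv_deg[:, None]
            verts[free] = 0.5 * (verts[free] + avg[free])
        d, cp = fld.closest(verts[free])
        move = np.zeros_like(verts[free])
        pos = d > 1e-12
        step = np.minimum(d[pos], cap)
        move[pos] = (cp[pos] - verts[free][pos]) * (step / d[pos])[:, None]
        verts[free] += move
        mesh._tri_cache = None  # vertices mutated in place

        classify_patches(wrap, fld, contact_dist)
        area = wrap.potential_area
        prev = wrap.area_history[-1]
        wrap.area_history.append(area)
        wrap.iteration = it
        if abs(area - prev) <= config.area_tol * max(prev, 1e-12):
            wrap.converged = True
            break
    if not wrap.converged:
        log.warning("shrink-wrap did not converge within %d iterations", config.max_iters)
    return wrap


def through_flow_normals(wrap: WrapSurface, occluder, flip: bool = False) -> np.ndarray:
    """Consistently oriented per-face normals pointing downstream.

    The cover's own winding gives consistent normals; the global sign is
    chosen so that on average they point from the cover toward the centroid
    of the occluder's bounding volume (i.e. into the valve, the direction
    regurgitant flow must traverse), with an override flag.
    """
    mesh = wrap.mesh
    tris = mesh.triangles
    v = mesh.vertices
    nrm = np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]])
    lens = np.linalg.norm(nrm, axis=1, keepdims=True)
    nrm = nrm / np.maximum(lens, 1e-300)
    occ = occluder.vertices if isinstance(occluder, SurfaceMesh) else None
    if occ is None:
        box_center = (occluder.centroids.min(axis=0) + occluder.centroids.max(axis=0)) / 2
    else:
        box_center = (occ.min(axis=0) + occ.max(axis=0)) / 2
    toward = box_center - v[tris].mean(axis=1)
    sign = np.sign(np.sum(nrm * toward))
    if sign == 0:
        sign = 1.0
    if flip:
        sign = -sign
    return sign * nrm


def raycast_filter(wrap: WrapSurface, occluder, config: RoaConfig) -> WrapSurface:
    """Relabel potential patches valid/invalid by cone ray casting.

    From each potential face centroid a deterministic, nested fan of
    ``n_rays`` directions inside a cone of apex angle ``cone_angle`` about
    the through-flow normal is cast against the occluder.  In the default
    (escape-validates) mode a face is a valid orifice patch as soon as one
    ray travels ``ray_max_length`` unobstructed; in the strict mode a single
    obstructed ray invalidates the face.
    """
    fld = _as_field(occluder)
    mesh = wrap.mesh
    pot = np.where(wrap.patch_label == POTENTIAL)[0]
    if len(pot) == 0:
        return wrap
    diag = np.linalg.norm(fld.centroids.max(axis=0) - fld.centroids.min(axis=0))
    tmax = config.ray_max_length if config.ray_max_length is not None else 4.0 * diag

    normals = through_flow_normals(wrap, occluder, config.flip_normal)[pot]
    centroids = mesh.face_centroids()[pot]
    eps = 0.01 * _mean_edge_length(mesh)
    origins = centroids + eps * normals

    half_angle = 0.5 * config.cone_angle
    canon = cone_directions(config.n_rays, np.array([0.0, 0.0, 1.0]), half_angle)
    # per-face orthonormal frame (e1, e2, n); matches the frame convention
    # used by cone_directions for a single axis
    helper = np.tile([1.0, 0.0, 0.0], (len(pot), 1))
    helper[np.abs(normals[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    e1 = np.cross(normals, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(normals, e1)

    undecided = np.arange(len(pot))
    escaped = np.zeros(len(pot), dtype=bool)
    hit_any = np.zeros(len(pot), dtype=bool)
    for k in range(config.n_rays):
        if len(undecided) == 0:
            break
        d = (canon[k, 0] * e1[undecided]
             + canon[k, 1] * e2[undecided]
             + canon[k, 2] * normals[undecided])
        hits = fld.rays_hit(origins[undecided], d, tmax)
        if config.escape_validates:
            newly = undecided[~hits]
            escaped[newly] = True
            undecided = undecided[hits]
        else:
            newly = undecided[hits]
            hit_any[newly] = True
            undecided = undecided[~hits]
    if config.escape_validates:
        valid = escaped
    else:
        valid = ~hit_any
    wrap.patch_label[pot[valid]] = VALID
    wrap.patch_label[pot[~valid]] = INVALID
    return wrap


# ---------------------------------------------------------------------------
# stage 7: assembly

def _valid_components(wrap: WrapSurface) -> list:
    """Edge-connected groups of valid faces (one group per orifice)."""
    mesh = wrap.mesh
    valid = np.where(wrap.patch_label == VALID)[0]
    if len(valid) == 0:
        return []
    pos = {int(f): i for i, f in enumerate(valid)}
    edge_owner: dict = {}
    rows, cols = [], []
    for f in valid:
        fv = mesh.faces[f]
        m = len(fv)
        for k in range(m):
            e = tuple(sorted((fv[k], fv[(k + 1) % m])))
            if e in edge_owner:
                rows.append(pos[int(f)])
                cols.append(edge_owner[e])
            else:
                edge_owner[e] = pos[int(f)]
    g = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(valid), len(valid)))
    n_comp, lbl = connected_components(g, directed=False)
    areas = wrap.face_areas()
    comps = []
    for c in range(n_comp):
        ids = valid[lbl == c]
        comps.append({
            "face_ids": ids.tolist(),
            "area_mm2": float(areas[ids].sum()),
            "n_faces": int(len(ids)),
        })
    comps.sort(key=lambda c: -c["area_mm2"])
    return comps


def compute_roa(leaflet: SurfaceMesh, landmarks: LandmarkSet, config: RoaConfig) -> OrificeResult:
    """Full ROA pipeline: inflate, contour, warp, shrink-wrap, ray-filter, sum."""
    occluder = inflate_surface(leaflet, config.thickness)
    fld = TriangleField(occluder.vertices, occluder.triangles)
    n_boundary = max(32, int(round(2.0 * np.sqrt(np.pi * config.remesh_vertices))))
    contour = build_contour(landmarks, n_samples=n_boundary)
    wrap = warp_disk_to_contour(contour, config.remesh_vertices)
    shrink_wrap(wrap, fld, config)
    potential_area = wrap.potential_area
    raycast_filter(wrap, fld, config)
    comps = _valid_components(wrap)
    roa = float(sum(c["area_mm2"] for c in comps))
    return OrificeResult(
        roa=roa,
        components=comps,
        potential_area=potential_area,
        wrap_area=wrap.mesh.area,
        converged=wrap.converged,
        iterations=wrap.iteration,
        config_echo=replace(config),
        wrap=wrap,
    )
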
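"""ROA pipeline stages: inflation, contour, disk warp, shrink-wrap, ray filter."""

import numpy as np
import pytest

from valvemetrics.geometry import TriangleField, cone_directions, triangle_areas
from valvemetrics.mesh_io import ContentError, LandmarkSet, SurfaceMesh
from valvemetrics.orifice import (
    CONTACT,
    INVALID,
    POTENTIAL,
    VALID,
    OrificeContour,
    RoaConfig,
    build_contour,
    classify_patches,
    compute_roa,
    inflate_surface,
    raycast_filter,
    shrink_wrap,
    warp_disk_to_contour,
)
from valvemetrics.synthetic import FixtureSpec, make_fixture


# ---------------------------------------------------------------------------
# configuration validation

def test_config_rejects_bad_values():
    with pytest.raises(ValueError):
        RoaConfig(n_rays=0)
    with pytest.raises(ValueError):
        RoaConfig(cone_angle=200.0)
    with pytest.raises(ValueError):
        RoaConfig(thickness=-1.0)


# ---------------------------------------------------------------------------
# inflation

def _icosphere(radius=5.0):
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=3, radius=radius)
    return SurfaceMesh(tm.vertices, [tuple(f) for f in tm.faces])


def test_inflated_sphere_shell_volume():
    """Inflating a radius-5 sphere by t=0.4 gives a shell whose enclosed
    volume difference matches 4/3 pi ((R+t/2)^3 - (R-t/2)^3)."""
    sphere = _icosphere(radius=5.0)
    shell = inflate_surface(sphere, 0.4)
    # shell = outer sphere + inner sphere (flipped): signed volume via trimesh
    tm = shell.as_trimesh()
    expected = 4.0 / 3.0 * np.pi * (5.2**3 - 4.8**3)
    # icosphere subdiv-3 underestimates the sphere by ~0.2%
    assert abs(tm.volume) == pytest.approx(expected, rel=0.02)


def test_inflated_plate_thickness_extent():
    fix = make_fixture(FixtureSpec(kind="intact_plate"))
    occ = inflate_surface(fix.mesh, 0.396)
    z = occ.vertices[:, 2]
    assert np.ptp(z) == pytest.approx(0.396, rel=1e-9)


def test_inflation_zero_thickness_is_identity():
    fix = make_fixture(FixtureSpec(kind="crease_trap"))
    occ = inflate_surface(fix.mesh, 0.0)
    assert occ.n_faces == fix.mesh.n_faces
    np.testing.assert_allclose(occ.vertices, fix.mesh.vertices)


def test_inflation_closes_open_boundaries():
    """A flat open square inflates to a watertight slab."""
    sq = SurfaceMesh([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
                     [(0, 1, 2), (0, 2, 3)])
    slab = inflate_surface(sq, 0.2)
    assert slab.as_trimesh().is_watertight
    assert abs(slab.as_trimesh().volume) == pytest.approx(1.0 * 1.0 * 0.2, rel=1e-9)


# ---------------------------------------------------------------------------
# contour

def test_contour_through_circle_landmarks_recovers_circle():
    theta = 2 * np.pi * np.arange(12) / 12
    lm = LandmarkSet(np.column_stack([10 * np.cos(theta), 10 * np.sin(theta),
                                      np.zeros(12)]))
    contour = build_contour(lm, n_samples=200)
    r = np.linalg.norm(contour.resampled_curve[:, :2], axis=1)
    assert np.abs(r - 10.0).max() < 0.05
    # approximately equal arc-length spacing
    seg = np.linalg.norm(np.diff(np.vstack([contour.resampled_curve,
                                            contour.resampled_curve[:1]]), axis=0), axis=1)
    assert seg.max() / seg.min() < 1.05


def test_contour_three_points_is_minimal_valid_input():
    lm = LandmarkSet([[0, 0, 0], [4, 0, 0], [0, 3, 0]])
    contour = build_contour(lm, n_samples=64)
    assert len(contour.resampled_curve) == 64


def test_contour_collinear_landmarks_rejected():
    lm = LandmarkSet([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ContentError):
        build_contour(lm)


def test_contour_duplicate_landmarks_rejected():
    lm = LandmarkSet([[0, 0, 0], [0, 0, 0], [1, 1, 0]])
    with pytest.raises(ContentError):
        build_contour(lm)


# ---------------------------------------------------------------------------
# disk warp

def _circle_contour(radius=10.0, n=128):
    theta = 2 * np.pi * np.arange(12) / 12
    lm = LandmarkSet(np.column_stack([radius * np.cos(theta),
                                      radius * np.sin(theta), np.zeros(12)]))
    return build_contour(lm, n_samples=n)


def test_warped_disk_area_matches_circle():
    wrap = warp_disk_to_contour(_circle_contour(radius=10.0), remesh_vertices=4000)
    assert wrap.mesh.area == pytest.approx(np.pi * 100.0, rel=0.01)
    assert wrap.mesh.n_vertices == pytest.approx(4000, rel=0.15)


def test_warp_boundary_interpolates_contour_exactly():
    contour = _circle_contour()
    wrap = warp_disk_to_contour(contour, 2000)
    b = wrap.mesh.vertices[wrap.boundary_vertices]
    assert len(b) == len(contour.resampled_curve)
    np.testing.assert_allclose(
        np.sort(np.linalg.norm(b[:, :2], axis=1)),
        np.sort(np.linalg.norm(contour.resampled_curve[:, :2], axis=1)),
        atol=1e-9)


def test_warp_of_planar_contour_stays_in_plane():
    """Harmonic interpolation of a planar boundary is planar (max principle)."""
    wrap = warp_disk_to_contour(_circle_contour(), 3000)
    assert np.abs(wrap.mesh.vertices[:, 2]).max() < 1e-9


def test_warp_deterministic():
    a = warp_disk_to_contour(_circle_contour(), 3000)
    b = warp_disk_to_contour(_circle_contour(), 3000)
    np.testing.assert_array_equal(a.mesh.vertices, b.mesh.vertices)


def test_warp_saddle_boundary_bounded_by_extremes():
    """For a non-planar boundary the harmonic interior obeys the discrete
    maximum principle: interior z lies within the boundary z range."""
    theta = 2 * np.pi * np.arange(16) / 16
    lm = LandmarkSet(np.column_stack([
        10 * np.cos(theta), 10 * np.sin(theta), 2.0 * np.cos(2 * theta)]))
    wrap = warp_disk_to_contour(build_contour(lm, 128), 3000)
    z = wrap.mesh.vertices[:, 2]
    zb = z[wrap.boundary_vertices]
    assert z.min() >= zb.min() - 1e-9
    assert z.max() <= zb.max() + 1e-9


# ---------------------------------------------------------------------------
# classification and shrink-wrap

def test_classify_against_flat_occluder():
    fix = make_fixture(FixtureSpec(kind="plate_hole"))
    occ = inflate_surface(fix.mesh, 0.396)
    wrap = warp_disk_to_contour(_circle_contour(radius=12.0), 2000)
    wrap.mesh.vertices[:, 2] = 0.396 / 2  # sit on the occluder top
    wrap.mesh._tri_cache = None
    classify_patches(wrap, occ, contact_dist=0.05)
    cent = wrap.mesh.face_centroids()
    inside_hole = np.linalg.norm(cent[:, :2], axis=1) < 5.0 - 0.2
    on_plate = np.linalg.norm(cent[:, :2], axis=1) > 5.0 + 0.2
    assert np.all(wrap.patch_label[inside_hole] == POTENTIAL)
    assert np.all(wrap.patch_label[on_plate] == CONTACT)


def test_shrink_wrap_converges_and_area_history_settles(hole_result):
    wrap = hole_result.wrap
    assert wrap.converged
    hist = np.asarray(wrap.area_history)
    assert len(hist) >= 2
    rel_last = abs(hist[-1] - hist[-2]) / hist[-2]
    assert rel_last <= 1e-3


def test_shrink_wrap_boundary_stays_pinned(hole_fixture, hole_config, hole_result):
    wrap = hole_result.wrap
    n_boundary = int(wrap.boundary_vertices.sum())
    contour = build_contour(hole_fixture.landmarks, n_samples=n_boundary)
    b = wrap.mesh.vertices[wrap.boundary_vertices]
    np.testing.assert_allclose(np.sort(np.linalg.norm(b[:, :2], axis=1)),
                               np.sort(np.linalg.norm(
                                   contour.resampled_curve[:, :2], axis=1)),
                               atol=1e-9)


def test_shrink_wrap_contact_faces_touch_occluder(hole_fixture, hole_result):
    occ = inflate_surface(hole_fixture.mesh, hole_result.config_echo.thickness)
    fld = TriangleField(occ.vertices, occ.triangles)
    wrap = hole_result.wrap
    cent = wrap.mesh.face_centroids()[wrap.patch_label == CONTACT]
    d = fld.distance(cent)
    assert np.percentile(d, 95) < 0.05  # essentially snapped onto the surface


def test_intact_plate_has_no_potential_area(intact_bundle):
    _, res = intact_bundle
    assert res.roa == 0.0
    assert res.components == []
    assert res.potential_area < 0.01 * res.wrap_area


# ---------------------------------------------------------------------------
# cone ray directions

def test_cone_directions_inside_cone_and_unit_length():
    axis = np.array([0.0, 0.0, 1.0])
    d = cone_directions(400, axis, 25.0)
    assert d.shape == (400, 3)
    np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
    cosines = d @ axis
    assert np.all(cosines >= np.cos(np.radians(25.0)) - 1e-12)
    np.testing.assert_allclose(d[0], axis, atol=1e-12)  # first ray is the axis


def test_cone_directions_are_prefix_nested():
    axis = np.array([0.0, 0.0, 1.0])
    d100 = cone_directions(100, axis, 25.0)
    d400 = cone_directions(400, axis, 25.0)
    np.testing.assert_array_equal(d100, d400[:100])


def test_raycast_open_half_space_all_valid():
    """A cover floating above a small distant occluder: every ray escapes."""
    wrap = warp_disk_to_contour(_circle_contour(radius=5.0), 500)
    wrap.mesh.vertices[:, 2] += 50.0
    wrap.mesh._tri_cache = None
    occ = SurfaceMesh([[-1, -1, 0], [1, -1, 0], [0, 1, 0]], [(0, 1, 2)])
    cfg = RoaConfig(remesh_vertices=500)
    raycast_filter(wrap, occ, cfg)
    assert np.all(wrap.patch_label == VALID)


def test_raycast_inside_closed_box_all_invalid():
    """A cover sealed inside a closed box: no ray can escape."""
    import trimesh

    box = trimesh.creation.box(extents=(30.0, 30.0, 30.0))
    occ = SurfaceMesh(box.vertices, [tuple(f) for f in box.faces])
    wrap = warp_disk_to_contour(_circle_contour(radius=5.0), 500)
    cfg = RoaConfig(remesh_vertices=500)
    raycast_filter(wrap, occ, cfg)
    assert np.all(wrap.patch_label == INVALID)


def test_raycast_valid_set_monotone_in_ray_count(trap_bundle):
    """With nested directions, faces validated at n rays stay validated at
    more rays (escape-validates mode only adds chances to escape)."""
    fld = trap_bundle["field"]
    cfg = trap_bundle["config"]
    wrap = trap_bundle["wrap"]
    valid_sets = []
    for n in (50, 200, 400):
        w = type(wrap)(mesh=wrap.mesh, patch_label=trap_bundle["pre_filter_labels"].copy(),
                       boundary_vertices=wrap.boundary_vertices)
        raycast_filter(w, fld, RoaConfig(thickness=cfg.thickness,
                                         remesh_vertices=cfg.remesh_vertices, n_rays=n))
        valid_sets.append(set(np.where(w.patch_label == VALID)[0]))
    assert valid_sets[0] <= valid_sets[1] <= valid_sets[2]


def test_strict_mode_rejects_shaft_faces(trap_bundle):
    """In strict (any-hit-invalidates) mode even the true slot is rejected,
    because oblique rays inside the collimating shaft always hit a wall."""
    wrap = trap_bundle["wrap"]
    cfg = trap_bundle["config"]
    w = type(wrap)(mesh=wrap.mesh, patch_label=trap_bundle["pre_filter_labels"].copy(),
                   boundary_vertices=wrap.boundary_vertices)
    raycast_filter(w, trap_bundle["field"],
                   RoaConfig(thickness=cfg.thickness, remesh_vertices=cfg.remesh_vertices,
                             escape_validates=False))
    strict_area = float(w.face_areas()[w.patch_label == VALID].sum())
    default_area = float(wrap.face_areas()[wrap.patch_label == VALID].sum())
    assert strict_area <= default_area
    assert strict_area == 0.0


# ---------------------------------------------------------------------------
# end-to-end invariants

def test_roa_area_ordering_invariant(hole_result):
    assert 0.0 <= hole_result.roa <= hole_result.potential_area
    assert hole_result.potential_area <= hole_result.wrap_area + 1e-9
    assert hole_result.roa == pytest.approx(
        sum(c["area_mm2"] for c in hole_result.components), rel=1e-12)


def test_single_hole_yields_single_component(hole_result, hole_fixture):
    assert len(hole_result.components) == 1
    assert hole_result.roa == pytest.approx(hole_fixture.truth.roa, rel=0.02)


def test_two_holes_yield_two_components_with_correct_ratio(two_hole_bundle):
    fix, res = two_hole_bundle
    assert len(res.components) == 2
    a_big, a_small = res.components[0]["area_mm2"], res.components[1]["area_mm2"]
    # radii 3 and 2 -> area ratio 9/4
    assert a_big / a_small == pytest.approx(9.0 / 4.0, rel=0.05)
    assert res.roa == pytest.approx(fix.truth.roa, rel=0.02)


def test_component_face_ids_partition_valid_faces(two_hole_bundle):
    _, res = two_hole_bundle
    all_ids = [i for c in res.components for i in c["face_ids"]]
    assert len(all_ids) == len(set(all_ids))
    valid_faces = set(np.where(res.wrap.patch_label == VALID)[0].tolist())
    assert set(all_ids) == valid_faces


def test_pipeline_deterministic(hole_fixture, hole_config, hole_result):
    again = compute_roa(hole_fixture.mesh, hole_fixture.landmarks, hole_config)
    assert again.roa == hole_result.roa
    np.testing.assert_array_equal(again.wrap.patch_label, hole_result.wrap.patch_label)
    np.testing.assert_array_equal(again.wrap.mesh.vertices, hole_result.wrap.mesh.vertices)


def test_roa_stable_under_cover_resolution(hole_fixture, hole_config, hole_result):
    finer = RoaConfig(thickness=hole_config.thickness, remesh_vertices=8000)
    res = compute_roa(hole_fixture.mesh, hole_fixture.landmarks, finer)
    assert res.roa == pytest.approx(hole_result.roa, rel=0.01)


def test_labeled_mesh_carries_patch_field(hole_result):
    out = hole_result.wrap.labeled_mesh()
    assert "patch_label" in out.cell_fields
    lbls = set(np.unique(out.cell_fields["patch_label"]).astype(int).tolist())
    assert lbls <= {CONTACT, POTENTIAL, VALID, INVALID}
    assert VALID in lbls and CONTACT in lbls
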
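"""Shared fixtures: the expensive ROA pipeline runs are computed once per
session and reused by unit, property and acceptance tests."""

import numpy as np
import pytest

from valvemetrics.geometry import TriangleField
from valvemetrics.orifice import (
    RoaConfig,
    build_contour,
    compute_roa,
    inflate_surface,
    raycast_filter,
    shrink_wrap,
    warp_disk_to_contour,
)
from valvemetrics.synthetic import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def hole_fixture():
    return make_fixture(FixtureSpec(kind="plate_hole"))


@pytest.fixture(scope="session")
def hole_config():
    return RoaConfig(thickness=0.396, remesh_vertices=4000)


@pytest.fixture(scope="session")
def hole_result(hole_fixture, hole_config):
    return compute_roa(hole_fixture.mesh, hole_fixture.landmarks, hole_config)


@pytest.fixture(scope="session")
def two_hole_bundle():
    fix = make_fixture(FixtureSpec(
        kind="plate_multi_hole", hole_radii=(2.0, 3.0),
        hole_centers=((-5.0, 0.0), (5.0, 0.0)),
        plate_radius=16.0, ring_radius=10.0))
    cfg = RoaConfig(thickness=fix.thickness, remesh_vertices=6000)
    return fix, compute_roa(fix.mesh, fix.landmarks, cfg)


@pytest.fixture(scope="session")
def intact_bundle():
    fix = make_fixture(FixtureSpec(kind="intact_plate"))
    cfg = RoaConfig(thickness=fix.thickness, remesh_vertices=3000)
    return fix, compute_roa(fix.mesh, fix.landmarks, cfg)


@pytest.fixture(scope="session")
def trap_bundle():
    """Crease trap: occluder field, shrink-wrapped cover (pre-filter labels),
    and the ray-filtered cover, exposed for oracle cross-checks."""
    fix = make_fixture(FixtureSpec(kind="crease_trap"))
    cfg = RoaConfig(thickness=0.0, remesh_vertices=8000)
    occluder = inflate_surface(fix.mesh, cfg.thickness)
    fld = TriangleField(occluder.vertices, occluder.triangles)
    n_boundary = max(32, int(round(2.0 * np.sqrt(np.pi * cfg.remesh_vertices))))
    contour = build_contour(fix.landmarks, n_samples=n_boundary)
    wrap = warp_disk_to_contour(contour, cfg.remesh_vertices)
    shrink_wrap(wrap, fld, cfg)
    pre_filter_labels = wrap.patch_label.copy()
    raycast_filter(wrap, fld, cfg)
    return {
        "fixture": fix,
        "config": cfg,
        "field": fld,
        "wrap": wrap,
        "pre_filter_labels": pre_filter_labels,
    }
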
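"""Functional and mechanical summary metrics from FE output fields.

Contact area is the integral of the contact surface over elements carrying
non-zero contact traction; stress/strain summaries are (by default)
area-weighted means of per-element principal values.  Fields arrive as
per-face cell data on a :class:`~valvemetrics.mesh_io.SurfaceMesh` (one
value per element), typically exported from the FE solver as VTP cell
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_io import SurfaceMesh

__all__ = ["MetricSummary", "contact_area", "field_mean", "summarize"]


class FieldError(KeyError):
    """A named cell field is missing from the mesh."""


@dataclass(frozen=True)
class MetricSummary:
    contact_area: float  # mm^2
    mean_p1_stress: float | None  # kPa
    mean_p1_strain: float | None  # dimensionless
    total_area: float  # mm^2


def _field(mesh: SurfaceMesh, name: str) -> np.ndarray:
    try:
        return mesh.cell_fields[name]
    except KeyError:
        raise FieldError(
            f"mesh has no cell field {name!r}; available: {sorted(mesh.cell_fields)}"
        ) from None


def contact_area(mesh: SurfaceMesh, traction_field_name: str, threshold: float = 0.0) -> float:
    """Total area (mm^2) of faces whose contact traction exceeds ``threshold``."""
    traction = _field(mesh, traction_field_name)
    return float(mesh.face_areas()[traction > threshold].sum())


def field_mean(mesh: SurfaceMesh, field_name: str, weighting: str = "area") -> float:
    """Mean of a per-face field, area-weighted (default) or uniform per element."""
    vals = _field(mesh, field_name)
    if weighting == "area":
        w = mesh.face_areas()
        return float(np.average(vals, weights=w))
    if weighting == "uniform":
        return float(vals.mean())
    raise ValueError(f"weighting must be 'area' or 'uniform', got {weighting!r}")


def summarize(
    mesh: SurfaceMesh,
    traction_field: str,
    stress_field: str | None = None,
    strain_field: str | None = None,
    threshold: float = 0.0,
    weighting: str = "area",
) -> MetricSummary:
    """Contact area plus optional principal stress/strain means in one record."""
    return MetricSummary(
        contact_area=contact_area(mesh, traction_field, threshold),
        mean_p1_stress=field_mean(mesh, stress_field, weighting) if stress_field else None,
        mean_p1_strain=field_mean(mesh, strain_field, weighting) if strain_field else None,
        total_area=mesh.area,
    )
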
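"""Surface-mesh and landmark I/O.

The package's geometric currency is :class:`SurfaceMesh`: vertices in
millimetres, triangle or quad faces, and optional named per-face scalar
fields (e.g. contact traction or principal stress exported from a finite
element solver as VTK PolyData cell data).

Formats: STL / PLY (via trimesh, triangles only), OBJ (quads preserved),
and VTK XML PolyData (.vtp) with CellData arrays.  Landmarks are read from
a plain JSON schema ``{"points": [[x,y,z], ...], "closed": true}`` or from
3D Slicer markup ``.fcsv`` files.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "LandmarkSet",
    "FormatError",
    "ContentError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
]


class FormatError(ValueError):
    """File could not be parsed as the declared format."""


class ContentError(ValueError):
    """File parsed but its content is unusable (empty mesh, too few points...)."""


@dataclass
class SurfaceMesh:
    """Triangle/quad surface mesh with optional per-face scalar fields."""

    vertices: np.ndarray
    faces: list
    cell_fields: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = [tuple(int(i) for i in f) for f in self.faces]
        for f in self.faces:
            if len(f) not in (3, 4):
                raise ContentError(f"faces must be triangles or quads, got {len(f)} vertices")
            if min(f) < 0 or max(f) >= len(self.vertices):
                raise ContentError("face index out of range")
        for name, vals in list(self.cell_fields.items()):
            vals = np.asarray(vals, dtype=np.float64).ravel()
            if len(vals) != len(self.faces):
                raise ContentError(
                    f"cell field {name!r} has {len(vals)} values for {len(self.faces)} faces"
                )
            self.cell_fields[name] = vals
        self._tri_cache = None

    # -- derived views -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _triangulate(self):
        if self._tri_cache is None:
            tris, owner = [], []
            for i, f in enumerate(self.faces):
                tris.append((f[0], f[1], f[2]))
                owner.append(i)
                if len(f) == 4:
                    tris.append((f[0], f[2], f[3]))
                    owner.append(i)
            self._tri_cache = (
                np.asarray(tris, dtype=np.int64).reshape(-1, 3),
                np.asarray(owner, dtype=np.int64),
            )
        return self._tri_cache

    @property
    def triangles(self) -> np.ndarray:
        """Triangulated view (quads split along the 0-2 diagonal), shape (m, 3)."""
        return self._triangulate()[0]

    @property
    def tri_to_face(self) -> np.ndarray:
        """Source face index of each triangle in :attr:`triangles`."""
        return self._triangulate()[1]

    def face_areas(self) -> np.ndarray:
        """Area per original face (quads as the sum of their two triangles)."""
        from .geometry import triangle_areas

        tri_area = triangle_areas(self.vertices, self.triangles)
        out = np.zeros(self.n_faces)
        np.add.at(out, self.tri_to_face, tri_area)
        return out

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_centroids(self) -> np.ndarray:
        return np.array([self.vertices[list(f)].mean(axis=0) for f in self.faces])

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(), process=False)

    def is_winding_consistent(self) -> bool:
        return bool(self.as_trimesh().is_winding_consistent)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            [tuple(f) for f in self.faces],
            {k: v.copy() for k, v in self.cell_fields.items()},
        )

    # -- cleaning --------------------------------------------------------

    def clean(self, merge_tol: float = 1e-8) -> "SurfaceMesh":
        """Merge duplicate vertices and drop zero-area faces (logged)."""
        key = np.round(self.vertices / max(merge_tol, 1e-300)).astype(np.int64)
        _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
        n_merged = self.n_vertices - len(first)
        verts = self.vertices[first]
        remap = inverse
        faces, keep = [], []
        for i, f in enumerate(self.faces):
            g = tuple(int(remap[j]) for j in f)
            if len(set(g)) < 3:
                continue
            faces.append(g)
            keep.append(i)
        mesh = SurfaceMesh(
            verts,
            faces,
            {k: v[keep] for k, v in self.cell_fields.items()},
        )
        areas = mesh.face_areas()
        live = areas > 0.0
        if not live.all():
            mesh = SurfaceMesh(
                mesh.vertices,
                [f for f, ok in zip(mesh.faces, live) if ok],
                {k: v[live] for k, v in mesh.cell_fields.items()},
            )
        n_dropped = self.n_faces - mesh.n_faces
        if n_merged or n_dropped:
            log.info("mesh clean: merged %d duplicate vertices, dropped %d degenerate faces",
                     n_merged, n_dropped)
        return mesh


@dataclass
class LandmarkSet:
    """Ordered 3D landmark points (mm) outlining a region of interest."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.closed and len(self.points) < 3:
            raise ContentError("a closed landmark set needs at least 3 points")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "LandmarkSet":
        return LandmarkSet(self.points @ np.asarray(rotation).T + np.asarray(translation),
                           closed=self.closed)


# ---------------------------------------------------------------------------
# mesh readers / writers

_EXT_FORMAT = {".stl": "stl", ".ply": "ply", ".obj": "obj", ".vtp": "vtp"}


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    try:
        return _EXT_FORMAT[path.suffix.lower()]
    except KeyError:
        raise FormatError(f"cannot infer mesh format from extension {path.suffix!r}")


def read_mesh(path, fmt: str = "auto", clean: bool = True) -> SurfaceMesh:
    """Read a surface mesh; ``fmt`` one of stl/ply/obj/vtp/auto."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, fmt)
    if fmt in ("stl", "ply"):
        try:
            tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
        except Exception as exc:  # noqa: BLE001 - normalize loader errors
            raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
        mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces, dtype=np.int64))
    elif fmt == "obj":
        mesh = _read_obj(path)
    elif fmt == "vtp":
        mesh = _read_vtp(path)
    else:
        raise FormatError(f"unknown mesh format {fmt!r}")
    if mesh.n_faces == 0:
        raise ContentError(f"{path} contains no faces")
    return mesh.clean() if clean else mesh


def write_mesh(mesh: SurfaceMesh, path, fmt: str = "auto") -> None:
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if mesh.n_faces == 0:
        raise ContentError("refusing to write a mesh with no faces")
    if fmt in ("stl", "ply", "obj") and mesh.cell_fields:
        log.warning("%s does not carry cell fields; dropping %s",
                    fmt, sorted(mesh.cell_fields))
    if fmt in ("stl", "ply"):
        mesh.as_trimesh().export(str(path), file_type=fmt)
    elif fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "vtp":
        _write_vtp(mesh, path)
    else:
        raise FormatError(f"unknown mesh format {fmt!r}")


def _read_obj(path: Path) -> SurfaceMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
                idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
                if len(idx) not in (3, 4):
                    raise FormatError(f"{path}: only triangle/quad faces supported")
                faces.append(tuple(idx))
    if not verts:
        raise FormatError(f"{path}: no vertices found in OBJ")
    return SurfaceMesh(np.asarray(verts), faces)


def _write_obj(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")


def _read_vtp(path: Path) -> SurfaceMesh:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"could not parse {path} as VTP XML: {exc}") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise FormatError(f"{path}: no <Piece> element in PolyData file")

    def _array(parent, name=None):
        if parent is None:
            return None
        for da in parent.findall("DataArray"):
            if name is None or da.get("Name") == name:
                if da.get("format", "ascii") != "ascii":
                    raise FormatError(f"{path}: only ascii-format VTP is supported")
                return np.fromstring(da.text or "", sep=" ")
        return None

    pts = _array(piece.find("Points"))
    if pts is None:
        raise FormatError(f"{path}: missing Points array")
    verts = pts.reshape(-1, 3)
    polys = piece.find("Polys")
    conn = _array(polys, "connectivity")
    offs = _array(polys, "offsets")
    if conn is None or offs is None:
        raise FormatError(f"{path}: missing Polys connectivity/offsets")
    conn = conn.astype(np.int64)
    offs = offs.astype(np.int64)
    faces, start = [], 0
    for end in offs:
        faces.append(tuple(conn[start:end]))
        start = int(end)
    fields = {}
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd.findall("DataArray"):
            fields[da.get("Name")] = np.fromstring(da.text or "", sep=" ")
    return SurfaceMesh(verts, faces, fields)


def _write_vtp(mesh: SurfaceMesh, path: Path) -> None:
    conn = " ".join(str(i) for f in mesh.faces for i in f)
    offsets, acc = [], 0
    for f in mesh.faces:
        acc += len(f)
        offsets.append(acc)
    pts = " ".join(f"{x:.17g}" for x in mesh.vertices.ravel())
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "  <PolyData>",
        f'    <Piece NumberOfPoints="{mesh.n_vertices}" NumberOfVerts="0" '
        f'NumberOfLines="0" NumberOfStrips="0" NumberOfPolys="{mesh.n_faces}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        f"          {pts}",
        "        </DataArray>",
        "      </Points>",
    ]
    if mesh.cell_fields:
        lines.append("      <CellData>")
        for name, vals in mesh.cell_fields.items():
            data = " ".join(f"{x:.17g}" for x in vals)
            lines += [
                f'        <DataArray type="Float64" Name="{name}" format="ascii">',
                f"          {data}",
                "        </DataArray>",
            ]
        lines.append("      </CellData>")
    lines += [
        "      <Polys>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        f"          {conn}",
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        f"          {' '.join(str(o) for o in offsets)}",
        "        </DataArray>",
        "      </Polys>",
        "    </Piece>",
        "  </PolyData>",
        "</VTKFile>",
        "",
    ]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# landmarks

def read_landmarks(path, fmt: str = "auto") -> LandmarkSet:
    """Read landmarks from JSON (``{"points": ..., "closed": ...}``) or Slicer FCSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "fcsv" if path.suffix.lower() == ".fcsv" else "json"
    if fmt == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"could not parse {path} as JSON: {exc}") from exc
        if isinstance(payload, list):
            pts, closed = payload, True
        else:
            pts, closed = payload.get("points", []), bool(payload.get("closed", True))
        if len(pts) < 3:
            raise ContentError(f"{path}: need at least 3 landmark points, got {len(pts)}")
        return LandmarkSet(np.asarray(pts, dtype=np.float64), closed=closed)
    if fmt == "fcsv":
        pts = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split(",")
            if len(cols) < 4:
                raise FormatError(f"{path}: malformed FCSV row {line!r}")
            pts.append([float(cols[1]), float(cols[2]), float(cols[3])])
        if len(pts) < 3:
            raise ContentError(f"{path}: need at least 3 landmark points, got {len(pts)}")
        return LandmarkSet(np.asarray(pts), closed=True)
    raise FormatError(f"unknown landmark format {fmt!r}")


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(
        {"points": landmarks.points.tolist(), "closed": landmarks.closed}, indent=1))
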
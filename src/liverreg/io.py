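"""Readers and writers for the interchange formats.

All formats are plain ASCII for determinism and diffability: VTK legacy for
surface and tet meshes (with face/tet labels as CELL_DATA), STL/PLY for
unlabeled surfaces (via trimesh), whitespace-delimited ``x y z label`` rows
for sparse patterns, one ``dx dy dz`` row per reference-mesh node for
displacement-field submissions, and 4x4 homogeneous matrices for rigid
transforms.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .fields import DisplacementField
from .geometry import (
    FEATURE_LABELS,
    FeaturePointCloud,
    InvalidInputError,
    RigidTransform,
    TetVolumeMesh,
    TriSurfaceMesh,
)


class FileFormatError(ValueError):
    """Raised for unsupported, corrupt, or truncated interchange files."""


# ---------------------------------------------------------------------------
# VTK legacy ASCII
# ---------------------------------------------------------------------------


def _write_vtk_header(fh, title: str):
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")


def write_surface_vtk(mesh: TriSurfaceMesh, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        _write_vtk_header(fh, "liverreg surface mesh")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if mesh.face_regions:
            fh.write(f"CELL_DATA {mesh.n_faces}\n")
            for name, idx in mesh.face_regions.items():
                flag = np.zeros(mesh.n_faces, dtype=int)
                flag[idx] = 1
                fh.write(f"SCALARS region_{name} int 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(str(int(x)) for x in flag) + "\n")


def write_volume_vtk(mesh: TetVolumeMesh, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        _write_vtk_header(fh, "liverreg tet mesh")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for v in mesh.nodes:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        fh.write("\n".join("10" for _ in range(mesh.n_tets)) + "\n")
        if mesh.tet_segments is not None:
            fh.write(f"CELL_DATA {mesh.n_tets}\n")
            fh.write("SCALARS segment int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(s)) for s in mesh.tet_segments) + "\n")


class _VtkTokens:
    """Token stream with byte-offset error context for legacy VTK files."""

    def __init__(self, path: Path):
        self.path = path
        text = path.read_text()
        self.tokens = []
        offset = 0
        for line in text.splitlines(keepends=True):
            stripped = line.split("#", 1)[0] if line.startswith("#") else line
            col = 0
            for tok in stripped.split():
                pos = offset + stripped.index(tok, col)
                col = stripped.index(tok, col) + len(tok)
                self.tokens.append((tok, pos))
            offset += len(line)
        self.i = 0

    def next(self, what: str = "token"):
        if self.i >= len(self.tokens):
            raise FileFormatError(
                f"{self.path}: truncated file, expected {what} at byte "
                f"{self.tokens[-1][1] if self.tokens else 0}"
            )
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_int(self, what: str) -> int:
        tok, pos = self.next(what)
        try:
            return int(tok)
        except ValueError as exc:
            raise FileFormatError(
                f"{self.path}: expected integer {what} at byte {pos}, got {tok!r}"
            ) from exc

    def expect_float(self, what: str) -> float:
        tok, pos = self.next(what)
        try:
            return float(tok)
        except ValueError as exc:
            raise FileFormatError(
                f"{self.path}: expected number {what} at byte {pos}, got {tok!r}"
            ) from exc


def _read_vtk(path: Path):
    text = path.read_text()
    lines = text.splitlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise FileFormatError(f"{path}: not a legacy VTK file")
    if lines[2].strip().upper() != "ASCII":
        raise FileFormatError(f"{path}: only ASCII VTK is supported")
    ts = _VtkTokens(path)
    # skip header tokens up to DATASET
    while True:
        tok, pos = ts.next("DATASET keyword")
        if tok.upper() == "DATASET":
            kind = ts.next("dataset kind")[0].upper()
            break
    tok = ts.next("POINTS keyword")[0].upper()
    if tok != "POINTS":
        raise FileFormatError(f"{path}: expected POINTS, got {tok}")
    n_pts = ts.expect_int("point count")
    ts.next("point dtype")
    pts = np.array(
        [[ts.expect_float("coordinate") for _ in range(3)] for _ in range(n_pts)]
    )
    return kind, ts, pts


def read_surface_vtk(path) -> TriSurfaceMesh:
    path = Path(path)
    kind, ts, pts = _read_vtk(path)
    if kind != "POLYDATA":
        raise FileFormatError(f"{path}: expected POLYDATA, got {kind}")
    tok = ts.next("POLYGONS keyword")[0].upper()
    if tok != "POLYGONS":
        raise FileFormatError(f"{path}: expected POLYGONS, got {tok}")
    n_faces = ts.expect_int("face count")
    ts.expect_int("polygon list size")
    faces = []
    for _ in range(n_faces):
        k = ts.expect_int("polygon vertex count")
        if k != 3:
            raise FileFormatError(f"{path}: only triangles supported, got {k}-gon")
        faces.append([ts.expect_int("face index") for _ in range(3)])
    regions = {}
    while ts.i < len(ts.tokens):
        tok = ts.next()[0].upper()
        if tok == "SCALARS":
            name = ts.next("array name")[0]
            ts.next("dtype")
            ts.next("components")
            ts.next("LOOKUP_TABLE")
            ts.next("table name")
            flags = np.array([ts.expect_int("cell value") for _ in range(n_faces)])
            if name.startswith("region_"):
                regions[name[len("region_"):]] = np.flatnonzero(flags)
    return TriSurfaceMesh(pts, np.asarray(faces), regions)


def read_volume_vtk(path) -> TetVolumeMesh:
    path = Path(path)
    kind, ts, pts = _read_vtk(path)
    if kind != "UNSTRUCTURED_GRID":
        raise FileFormatError(f"{path}: expected UNSTRUCTURED_GRID, got {kind}")
    tok = ts.next("CELLS keyword")[0].upper()
    if tok != "CELLS":
        raise FileFormatError(f"{path}: expected CELLS, got {tok}")
    n_cells = ts.expect_int("cell count")
    ts.expect_int("cell list size")
    tets = []
    for _ in range(n_cells):
        k = ts.expect_int("cell node count")
        if k != 4:
            raise FileFormatError(f"{path}: only tetrahedra supported, got {k} nodes")
        tets.append([ts.expect_int("node index") for _ in range(4)])
    segments = None
    while ts.i < len(ts.tokens):
        tok = ts.next()[0].upper()
        if tok == "SCALARS":
            name = ts.next("array name")[0]
            ts.next("dtype")
            ts.next("components")
            ts.next("LOOKUP_TABLE")
            ts.next("table name")
            vals = np.array([ts.expect_int("cell value") for _ in range(n_cells)])
            if name == "segment":
                segments = vals
    mesh = TetVolumeMesh(pts, np.asarray(tets))
    mesh.tet_segments = segments
    return mesh


# ---------------------------------------------------------------------------
# Generic mesh entry points
# ---------------------------------------------------------------------------


def read_mesh(path):
    """Read a surface (VTK/STL/PLY) or tet (VTK) mesh by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        kind = None
        for line in path.read_text().splitlines():
            if line.upper().startswith("DATASET"):
                kind = line.split()[1].upper()
                break
        if kind == "POLYDATA":
            return read_surface_vtk(path)
        if kind == "UNSTRUCTURED_GRID":
            return read_volume_vtk(path)
        raise FileFormatError(f"{path}: unsupported VTK dataset {kind}")
    if suffix in (".stl", ".ply"):
        import trimesh

        m = trimesh.load(path, force="mesh", process=False)
        return TriSurfaceMesh(np.asarray(m.vertices, float), np.asarray(m.faces))
    raise FileFormatError(f"{path}: unsupported mesh format {suffix!r}")


def write_mesh(mesh, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        if isinstance(mesh, TetVolumeMesh):
            write_volume_vtk(mesh, path)
        else:
            write_surface_vtk(mesh, path)
        return
    if suffix in (".stl", ".ply"):
        mesh.as_trimesh().export(path)
        return
    raise FileFormatError(f"{path}: unsupported mesh format {suffix!r}")


# ---------------------------------------------------------------------------
# Sparse patterns, submissions, transforms
# ---------------------------------------------------------------------------


def write_pattern(cloud: FeaturePointCloud, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for p, lab in zip(cloud.points, cloud.labels):
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {lab}\n")


def read_pattern(path) -> FeaturePointCloud:
    path = Path(path)
    pts, labs = [], []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FileFormatError(f"{path}:{ln}: expected 'x y z label' row")
        try:
            pts.append([float(x) for x in parts[:3]])
        except ValueError as exc:
            raise FileFormatError(f"{path}:{ln}: bad coordinate") from exc
        if parts[3] not in FEATURE_LABELS:
            raise FileFormatError(
                f"{path}:{ln}: unknown label {parts[3]!r}; "
                f"expected one of {FEATURE_LABELS}"
            )
        labs.append(parts[3])
    if not pts:
        raise FileFormatError(f"{path}: empty pattern file")
    return FeaturePointCloud(np.asarray(pts), np.asarray(labs))


def write_submission(field: DisplacementField, path) -> None:
    """One 'dx dy dz' row per reference-mesh node, in node order."""
    path = Path(path)
    np.savetxt(path, field.values, fmt="%.9g")


def read_submission(path, mesh: TetVolumeMesh | None = None) -> DisplacementField:
    path = Path(path)
    try:
        values = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise FileFormatError(f"{path}: malformed submission file") from exc
    if values.shape[1] != 3:
        raise FileFormatError(f"{path}: expected 3 columns, got {values.shape[1]}")
    if mesh is not None and len(values) != mesh.n_nodes:
        raise FileFormatError(
            f"{path}: {len(values)} rows but mesh has {mesh.n_nodes} nodes"
        )
    return DisplacementField(values)


def write_transform(transform: RigidTransform, path) -> None:
    np.savetxt(Path(path), transform.as_matrix(), fmt="%.12g")


def read_transform(path) -> RigidTransform:
    M = np.loadtxt(Path(path))
    if M.shape != (4, 4):
        raise FileFormatError(f"{path}: expected a 4x4 matrix")
    try:
        return RigidTransform.from_matrix(M)
    except InvalidInputError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def file_checksum(path) -> str:
    """SHA-256 of a file, for run-log provenance."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
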
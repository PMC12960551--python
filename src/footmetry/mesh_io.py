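"""Surface-mesh, landmark and report file I/O.

Formats
-------
* Triangle meshes: STL (binary and ASCII) and ASCII PLY.  All coordinates are
  interpreted as millimetres; there is no unit autodetection.
* Landmarks: CSV with columns ``id,x,y,z`` or a JSON object, restricted to the
  six fixed anatomical ids (``HEEL, MT1, MT5, ARCH, MED_MAL, LAT_MAL``).
* Measurement / tolerance reports: CSV (``name,value,units`` rows) or JSON.
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import LandmarkSchemaError, MeshFormatError, MissingLandmarkError

__all__ = [
    "TriangleMesh",
    "LandmarkSet",
    "MeasurementReport",
    "LANDMARK_IDS",
    "CORE_LANDMARK_IDS",
    "MEASUREMENT_UNITS",
    "MEASUREMENT_NAMES",
    "read_triangle_mesh",
    "write_triangle_mesh",
    "read_landmark_set",
    "write_landmark_set",
    "write_report",
    "read_report",
]

#: Fixed anatomical landmark identifiers.
LANDMARK_IDS = ("HEEL", "MT1", "MT5", "ARCH", "MED_MAL", "LAT_MAL")

#: Landmarks required by the measurement pipeline (malleoli are optional).
CORE_LANDMARK_IDS = ("HEEL", "MT1", "MT5", "ARCH")

#: The 15 named measurements and their units.
MEASUREMENT_UNITS: Dict[str, str] = {
    "foot_length": "mm",
    "heel_to_mt1_length": "mm",
    "heel_to_mt5_length": "mm",
    "dist_mt1_heel": "mm",
    "dist_mt1_mt5": "mm",
    "dist_mt5_heel": "mm",
    "forefoot_width": "mm",
    "midfoot_width": "mm",
    "heel_width": "mm",
    "forefoot_girth": "mm",
    "midfoot_girth": "mm",
    "hindfoot_girth": "mm",
    "arch_height_index": "ratio",
    "arch_height": "mm",
    "ankle_angle": "deg",
}

MEASUREMENT_NAMES: Tuple[str, ...] = tuple(MEASUREMENT_UNITS)

_MERGE_TOL = 1e-6  # mm; duplicate-vertex merge tolerance for readers


@dataclass
class TriangleMesh:
    """Triangle surface mesh in millimetres.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    name : free-text identifier
    meta : optional provenance (generator parameters, resolution, ...)
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError("mesh contains non-finite vertex coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshFormatError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """Axis-aligned bounding box as a (2, 3) array: [min; max]."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalize:
            lens = np.linalg.norm(n, axis=1)
            lens[lens == 0] = 1.0
            n = n / lens[:, None]
        return n

    def validate_for_measurement(self) -> None:
        """Enforce the stricter invariants needed before measuring."""
        if self.n_vertices < 4 or self.n_faces < 4:
            raise MeshFormatError(
                f"mesh '{self.name}' too small for measurement: "
                f"{self.n_vertices} vertices, {self.n_faces} faces"
            )

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.name, dict(self.meta)
        )


@dataclass
class LandmarkSet:
    """Named anatomical 3-D points (millimetres).

    ``points`` maps landmark ids to (3,) arrays; ``source`` records whether the
    landmarks were palpation-guided or scan-derived.
    """

    points: Dict[str, np.ndarray]
    side: str = "right"
    source: str = "guided"

    def __post_init__(self) -> None:
        clean: Dict[str, np.ndarray] = {}
        for lid, p in self.points.items():
            if lid not in LANDMARK_IDS:
                raise LandmarkSchemaError(f"unknown landmark id {lid!r}")
            arr = np.asarray(p, dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise LandmarkSchemaError(f"non-finite coordinate for {lid}")
            clean[lid] = arr
        self.points = clean
        if self.side not in ("left", "right"):
            raise LandmarkSchemaError(f"side must be left|right, got {self.side!r}")

    def __getitem__(self, lid: str) -> np.ndarray:
        try:
            return self.points[lid]
        except KeyError:
            raise MissingLandmarkError(f"landmark {lid} not present") from None

    def __contains__(self, lid: str) -> bool:
        return lid in self.points

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(self.points)

    @property
    def is_partial(self) -> bool:
        """True when one or both malleoli are absent."""
        return not ("MED_MAL" in self.points and "LAT_MAL" in self.points)

    def require(self, *lids: str) -> None:
        missing = [lid for lid in lids if lid not in self.points]
        if missing:
            raise MissingLandmarkError(f"missing landmarks: {', '.join(missing)}")

    def transform(self, t) -> "LandmarkSet":
        """Apply a rigid transform (any object with ``.apply(points)``)."""
        return LandmarkSet(
            {lid: t.apply(p) for lid, p in self.points.items()},
            side=self.side,
            source=self.source,
        )

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            {lid: p.copy() for lid, p in self.points.items()},
            side=self.side,
            source=self.source,
        )


@dataclass
class MeasurementReport:
    """The 15 named foot measurements plus provenance.

    ``values`` is keyed by :data:`MEASUREMENT_NAMES` in order; entries may be
    ``None`` when a malleoli-dependent measurement could not be computed (the
    corresponding flag is recorded in ``flags``).
    """

    values: Dict[str, Optional[float]]
    mesh_name: str = ""
    landmark_source: str = ""
    condition: str = ""
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals: Dict[str, Optional[float]] = {}
        for name in MEASUREMENT_NAMES:
            if name not in self.values:
                raise ValueError(f"report missing measurement {name!r}")
            v = self.values[name]
            vals[name] = None if v is None else float(v)
        extra = set(self.values) - set(MEASUREMENT_NAMES)
        if extra:
            raise ValueError(f"unknown measurement fields: {sorted(extra)}")
        self.values = vals
        self.flags = tuple(self.flags)

    def __getattr__(self, name: str):
        values = self.__dict__.get("values")
        if values is not None and name in values:
            return values[name]
        raise AttributeError(name)

    def validate(self) -> None:
        """Check value ranges for all computed measurements."""
        for name, v in self.values.items():
            if v is None:
                continue
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite")
            if name == "arch_height_index":
                if not (0.0 <= v < 1.0):
                    raise ValueError(f"arch_height_index out of [0,1): {v}")
            elif name == "ankle_angle":
                if not (0.0 <= v < 90.0):
                    raise ValueError(f"ankle_angle out of [0,90): {v}")
            elif name == "arch_height":
                if v < 0:
                    raise ValueError(f"arch_height negative: {v}")
            elif v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    def to_rows(self) -> Iterable[Tuple[str, Optional[float], str]]:
        for name in MEASUREMENT_NAMES:
            yield name, self.values[name], MEASUREMENT_UNITS[name]

    def meta(self) -> Dict[str, object]:
        return {
            "mesh_name": self.mesh_name,
            "landmark_source": self.landmark_source,
            "condition": self.condition,
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# mesh readers / writers
# ---------------------------------------------------------------------------


def _merge_vertices(raw: np.ndarray, faces: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Merge duplicate vertices within 1e-6 mm; drop degenerate faces."""
    if len(raw) == 0:
        return raw, faces
    key = np.round(raw / _MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = raw[first]
    faces = inverse[faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return verts, faces[ok]


def _read_stl_ascii(text: str, name: str) -> TriangleMesh:
    coords = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) == 4 and parts[0].lower() == "vertex":
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as e:
                raise MeshFormatError(f"bad vertex line in ASCII STL: {line!r}") from e
    if not coords or len(coords) % 3 != 0:
        raise MeshFormatError("ASCII STL contains no complete facets")
    raw = np.asarray(coords, dtype=np.float64)
    faces = np.arange(len(raw), dtype=np.int64).reshape(-1, 3)
    verts, faces = _merge_vertices(raw, faces)
    if len(faces) == 0:
        raise MeshFormatError("ASCII STL has zero non-degenerate facets")
    return TriangleMesh(verts, faces, name)


_STL_RECORD = np.dtype(
    [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
)


def _read_stl_binary(data: bytes, name: str) -> TriangleMesh:
    if len(data) < 84:
        raise MeshFormatError("binary STL shorter than 84-byte header")
    (count,) = struct.unpack("<I", data[80:84])
    need = 84 + count * 50
    if count == 0:
        raise MeshFormatError("binary STL declares zero facets")
    if len(data) < need:
        raise MeshFormatError(
            f"truncated binary STL: {count} facets declared, "
            f"{(len(data) - 84) // 50} present"
        )
    rec = np.frombuffer(data[84:need], dtype=_STL_RECORD)
    raw = rec["v"].astype(np.float64).reshape(-1, 3)
    faces = np.arange(len(raw), dtype=np.int64).reshape(-1, 3)
    verts, faces = _merge_vertices(raw, faces)
    if len(faces) == 0:
        raise MeshFormatError("binary STL has zero non-degenerate facets")
    return TriangleMesh(verts, faces, name)


def _read_stl(path: Path) -> TriangleMesh:
    data = path.read_bytes()
    head = data[:512].lstrip()
    if head.startswith(b"solid") and b"facet" in data:
        try:
            return _read_stl_ascii(data.decode("ascii", errors="replace"), path.stem)
        except MeshFormatError:
            pass  # files can start with "solid" yet be binary
    return _read_stl_binary(data, path.stem)


def _read_ply(path: Path) -> TriangleMesh:
    with open(path, "r", errors="replace") as fh:
        magic = fh.readline().strip()
        if magic != "ply":
            raise MeshFormatError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        fmt_seen = False
        vert_props: list[str] = []
        element = None
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format":
                if tok[1] != "ascii":
                    raise MeshFormatError("only ASCII PLY is supported")
                fmt_seen = True
            elif tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vert = int(tok[2])
                elif element == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and element == "vertex":
                vert_props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        if not fmt_seen:
            raise MeshFormatError("PLY header missing format line")
        for ax in ("x", "y", "z"):
            if ax not in vert_props:
                raise MeshFormatError(f"PLY vertex element missing property {ax}")
        ix = [vert_props.index(ax) for ax in ("x", "y", "z")]
        verts = np.empty((n_vert, 3), dtype=np.float64)
        for i in range(n_vert):
            vals = fh.readline().split()
            if len(vals) < len(vert_props):
                raise MeshFormatError("PLY vertex data truncated")
            verts[i] = [float(vals[j]) for j in ix]
        faces = []
        for _ in range(n_face):
            vals = fh.readline().split()
            if not vals:
                raise MeshFormatError("PLY face data truncated")
            cnt = int(vals[0])
            if cnt != 3:
                raise MeshFormatError("only triangular PLY faces are supported")
            faces.append([int(v) for v in vals[1:4]])
    if n_face == 0:
        raise MeshFormatError("PLY has zero faces")
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64), path.stem)


def read_triangle_mesh(path, fmt: str = "auto") -> TriangleMesh:
    """Read an STL (binary or ASCII) or ASCII PLY mesh.

    Duplicate vertices are merged within 1e-6 mm.  Raises
    :class:`MeshFormatError` for malformed files and propagates ``OSError``
    for unreadable paths.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lower().lstrip(".") or "stl"
    if fmt == "stl":
        return _read_stl(path)
    if fmt == "ply":
        return _read_ply(path)
    raise MeshFormatError(f"unsupported mesh format {fmt!r}")


def _write_stl_binary(mesh: TriangleMesh, path: Path) -> None:
    rec = np.zeros(mesh.n_faces, dtype=_STL_RECORD)
    rec["normal"] = mesh.face_normals().astype(np.float32)
    rec["v"] = mesh.vertices[mesh.faces].astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(b"footmetry binary STL".ljust(80, b" "))
        fh.write(struct.pack("<I", mesh.n_faces))
        fh.write(rec.tobytes())


def _write_stl_ascii(mesh: TriangleMesh, path: Path) -> None:
    normals = mesh.face_normals()
    tri = mesh.vertices[mesh.faces]
    with open(path, "w") as fh:
        fh.write(f"solid {mesh.name or 'footmetry'}\n")
        for n, t in zip(normals, tri):
            fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
            fh.write("    outer loop\n")
            for v in t:
                fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {mesh.name or 'footmetry'}\n")


def _write_ply(
    mesh: TriangleMesh,
    path: Path,
    vertex_scalars: Optional[Mapping[str, Sequence[float]]] = None,
) -> None:
    scalars = dict(vertex_scalars or {})
    for name, vals in scalars.items():
        if len(vals) != mesh.n_vertices:
            raise ValueError(f"scalar {name!r} length != vertex count")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment {mesh.name or 'footmetry'}\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        for name in scalars:
            fh.write(f"property double {name}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        cols = [mesh.vertices] + [
            np.asarray(scalars[n], dtype=np.float64).reshape(-1, 1) for n in scalars
        ]
        for row in np.hstack(cols):
            fh.write(" ".join(f"{v:.9e}" for v in row) + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_triangle_mesh(
    mesh: TriangleMesh,
    path,
    fmt: str = "auto",
    vertex_scalars: Optional[Mapping[str, Sequence[float]]] = None,
) -> None:
    """Write a mesh as binary STL (default), ASCII STL or ASCII PLY.

    ``fmt`` may be ``stl`` (binary), ``stl_ascii`` or ``ply``; ``auto`` picks
    by file suffix.  ``vertex_scalars`` attaches per-vertex scalar properties
    (PLY only, e.g. deviation colour maps).
    """
    if mesh.n_faces == 0:
        raise MeshFormatError("refusing to write mesh with zero faces")
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lower().lstrip(".") or "stl"
    if fmt == "stl":
        _write_stl_binary(mesh, path)
    elif fmt == "stl_ascii":
        _write_stl_ascii(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path, vertex_scalars)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# landmark readers / writers
# ---------------------------------------------------------------------------


def _landmarks_from_records(
    records: Iterable[Tuple[str, object, object, object]],
    side: str,
    source: str,
) -> LandmarkSet:
    points: Dict[str, np.ndarray] = {}
    for lid, x, y, z in records:
        lid = str(lid).strip()
        if lid not in LANDMARK_IDS:
            raise LandmarkSchemaError(f"unknown landmark id {lid!r}")
        if lid in points:
            raise LandmarkSchemaError(f"duplicate landmark id {lid!r}")
        try:
            points[lid] = np.array([float(x), float(y), float(z)])
        except (TypeError, ValueError) as e:
            raise LandmarkSchemaError(f"non-numeric coordinate for {lid}") from e
    missing_core = [lid for lid in CORE_LANDMARK_IDS if lid not in points]
    if missing_core:
        raise LandmarkSchemaError(
            f"missing required landmarks: {', '.join(missing_core)}"
        )
    return LandmarkSet(points, side=side, source=source)


def read_landmark_set(path, fmt: str = "auto") -> LandmarkSet:
    """Read a landmark file (CSV ``id,x,y,z`` or JSON object keyed by id).

    The four core landmarks are required; absent malleoli leave the set
    flagged partial (:attr:`LandmarkSet.is_partial`).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            rows = [r for r in reader if r and not r[0].startswith("#")]
        if not rows:
            raise LandmarkSchemaError(f"empty landmark file {path}")
        header = [c.strip().lower() for c in rows[0]]
        if header[:4] != ["id", "x", "y", "z"]:
            raise LandmarkSchemaError("landmark CSV header must be id,x,y,z")
        records = []
        for r in rows[1:]:
            if len(r) < 4:
                raise LandmarkSchemaError(f"short landmark row: {r}")
            records.append((r[0], r[1], r[2], r[3]))
        return _landmarks_from_records(records, side="right", source="guided")
    if fmt == "json":
        with open(path) as fh:
            obj = json.load(fh)
        pts = obj.get("landmarks", obj)
        side = obj.get("side", "right") if isinstance(obj, dict) else "right"
        source = obj.get("source", "guided") if isinstance(obj, dict) else "guided"
        records = []
        for lid, xyz in pts.items():
            if lid in ("side", "source"):
                continue
            if not isinstance(xyz, (list, tuple)) or len(xyz) != 3:
                raise LandmarkSchemaError(f"landmark {lid!r} must map to [x,y,z]")
            records.append((lid, *xyz))
        return _landmarks_from_records(records, side=side, source=source)
    raise LandmarkSchemaError(f"unsupported landmark format {fmt!r}")


def write_landmark_set(landmarks: LandmarkSet, path, fmt: str = "auto") -> None:
    """Write a landmark set as CSV or JSON (schema mirrors the reader)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "x", "y", "z"])
            for lid in LANDMARK_IDS:
                if lid in landmarks:
                    p = landmarks[lid]
                    w.writerow([lid, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])
    elif fmt == "json":
        obj = {
            "side": landmarks.side,
            "source": landmarks.source,
            "landmarks": {
                lid: [float(v) for v in landmarks[lid]]
                for lid in LANDMARK_IDS
                if lid in landmarks
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")
    else:
        raise LandmarkSchemaError(f"unsupported landmark format {fmt!r}")


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def write_report(report, path, fmt: str = "auto") -> None:
    """Write a measurement report or tolerance summary.

    Any object exposing ``to_rows()`` (name, value, units triples) and
    ``meta()`` is accepted.  CSV output has one data row per named value;
    JSON output round-trips losslessly via :func:`read_report`.
    Non-finite values are rejected.
    """
    rows = list(report.to_rows())
    for name, value, _ in rows:
        if value is not None and not np.isfinite(value):
            raise ValueError(f"report value {name!r} is not finite")
    path = Path(path)
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            for key, val in report.meta().items():
                fh.write(f"# {key}: {val}\n")
            w = csv.writer(fh)
            w.writerow(["name", "value", "units"])
            for name, value, units in rows:
                w.writerow([name, "" if value is None else f"{value:.4f}", units])
    elif fmt == "json":
        obj = {
            "meta": report.meta(),
            "values": {name: value for name, value, _ in rows},
            "units": {name: units for name, _, units in rows},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unsupported report format {fmt!r}")


def read_report(path) -> MeasurementReport:
    """Read a JSON measurement report written by :func:`write_report`."""
    with open(path) as fh:
        obj = json.load(fh)
    meta = obj.get("meta", {})
    return MeasurementReport(
        values=obj["values"],
        mesh_name=meta.get("mesh_name", ""),
        landmark_source=meta.get("landmark_source", ""),
        condition=meta.get("condition", ""),
        flags=tuple(meta.get("flags", ())),
    )
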
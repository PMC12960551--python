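"""The 15 foot measurements computed from a registered mesh + landmarks.

All operations assume the scene has been registered (plantar plane on z = 0,
heel at the origin, toes towards +Y); :func:`measure_foot` performs the
registration itself and then orchestrates every measurement.

Measurement definitions
-----------------------
1.  foot_length          Y extent of the bounding box after trimming the scan
                         above the mean malleoli height.
2.  heel_to_mt1_length   Y distance from the box rear face to MT1.
3.  heel_to_mt5_length   Y distance from the box rear face to MT5.
4-6. landmark distances  3-D Euclidean distances HEEL-MT1, MT1-MT5, MT5-HEEL.
7.  forefoot_width       distance between the z=0 projections of MT1 and MT5.
8.  midfoot_width        X-parallel chord of the plantar trace through the
                         projected arch point.
9.  heel_width           X-parallel chord through the projected heel point.
10. forefoot_girth       section perimeter on the vertical plane through
                         MT1 and MT5.
11. midfoot_girth        section perimeter on the Y-normal plane through the
                         midpoint of HEEL and MT1.
12. hindfoot_girth       section perimeter on the inclined plane through the
                         rear heel surface point and the midpoint of MED_MAL
                         and ARCH, containing the X direction.
13. arch_height_index    arch_height / heel_to_mt1_length.
14. arch_height          z of the arch point above the plantar plane.
15. ankle_angle          angle between HEEL->malleoli-midpoint and vertical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import linemerge

from ._geometry import plane_section_loops, polyline_length
from .errors import (
    EmptyTraceError,
    GeometryError,
    MeasurementError,
    MissingLandmarkError,
    OpenSectionError,
)
from .mesh_io import MEASUREMENT_NAMES, LandmarkSet, MeasurementReport, TriangleMesh
from .registration import register_scene

__all__ = [
    "PlantarTrace",
    "SectionPlane",
    "plantar_trace",
    "cross_section_perimeter",
    "foot_length",
    "truncated_lengths",
    "landmark_distances",
    "widths",
    "girths",
    "arch_metrics",
    "ankle_angle",
    "measure_foot",
    "DEFAULT_HEIGHT_CUTOFF",
]

#: Fallback plantar-trace cutoff when malleoli are absent (mm).
DEFAULT_HEIGHT_CUTOFF = 40.0

#: Half-width of the X slab used to locate the rear heel surface point (mm).
_HEEL_SLAB_HALF_WIDTH = 5.0


@dataclass
class PlantarTrace:
    """Plantar silhouette polygon in the world XY plane."""

    polygon: Polygon
    height_cutoff: float

    @property
    def area(self) -> float:
        return float(self.polygon.area)


@dataclass
class SectionPlane:
    """Cutting plane with an anchor used to select among section loops."""

    point: np.ndarray
    normal: np.ndarray
    anchor: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        ln = np.linalg.norm(n)
        if ln < 1e-12:
            raise GeometryError("section plane normal has zero length")
        self.normal = n / ln
        self.anchor = np.asarray(self.anchor, dtype=np.float64).reshape(3)


def plantar_trace(mesh: TriangleMesh, height_cutoff: float) -> PlantarTrace:
    """Project all faces fully below ``height_cutoff`` to z=0 and union them.

    Returns the largest connected component of the union as the trace.
    """
    if height_cutoff <= 0:
        raise GeometryError(f"height cutoff must be positive, got {height_cutoff}")
    z = mesh.vertices[:, 2]
    below = np.all(z[mesh.faces] < height_cutoff, axis=1)
    if not below.any():
        raise EmptyTraceError(f"no faces fully below z = {height_cutoff} mm")
    tri2d = mesh.vertices[mesh.faces[below]][:, :, :2]
    # drop degenerate projections (vertical faces)
    ab = tri2d[:, 1] - tri2d[:, 0]
    ac = tri2d[:, 2] - tri2d[:, 0]
    area2 = np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    tri2d = tri2d[area2 > 1e-10]
    if len(tri2d) == 0:
        raise EmptyTraceError("all faces below the cutoff project to zero area")
    rings = np.concatenate([tri2d, tri2d[:, :1, :]], axis=1)
    polys = shapely.polygons(rings)
    try:
        union = shapely.union_all(polys)
    except shapely.errors.GEOSException:
        # rare near-degenerate soups: snap-round a validated union
        union = shapely.union_all(shapely.make_valid(polys), grid_size=1e-9)
    if union.geom_type == "Polygon":
        poly = union
    elif union.geom_type == "MultiPolygon":
        poly = max(union.geoms, key=lambda g: g.area)
    else:
        candidates = [g for g in getattr(union, "geoms", []) if g.geom_type == "Polygon"]
        if not candidates:
            raise EmptyTraceError("trace union produced no polygonal component")
        poly = max(candidates, key=lambda g: g.area)
    if poly.area <= 0:
        raise EmptyTraceError("trace polygon has zero area")
    return PlantarTrace(polygon=poly, height_cutoff=float(height_cutoff))


def cross_section_perimeter(
    mesh: TriangleMesh, plane: SectionPlane, return_loop: bool = False
):
    """Perimeter of the mesh--plane section loop nearest the plane anchor.

    Raises :class:`OpenSectionError` when the plane yields no closed loop.
    """
    loops = plane_section_loops(mesh.vertices, mesh.faces, plane.point, plane.normal)
    closed = [pts for pts, is_closed in loops if is_closed and len(pts) >= 3]
    if not closed:
        raise OpenSectionError("plane does not intersect the mesh in a closed loop")
    centroids = [pts.mean(axis=0) for pts in closed]
    best = int(
        np.argmin([np.linalg.norm(c - plane.anchor) for c in centroids])
    )
    length = polyline_length(closed[best], closed=True)
    if return_loop:
        return length, closed[best]
    return length


def _trimmed_vertices(mesh: TriangleMesh, landmarks: LandmarkSet) -> np.ndarray:
    z_cut = 0.5 * (landmarks["MED_MAL"][2] + landmarks["LAT_MAL"][2])
    keep = mesh.vertices[mesh.vertices[:, 2] <= z_cut]
    if len(keep) == 0:
        raise GeometryError("no vertices below the malleoli height")
    return keep


def foot_length(
    mesh: TriangleMesh, landmarks: LandmarkSet
) -> Tuple[float, bool]:
    """Y extent of the malleoli-trimmed bounding box.

    Returns ``(length, untrimmed)``; ``untrimmed`` is True when the malleoli
    were absent and the full bounding box was used instead.
    """
    if "MED_MAL" in landmarks and "LAT_MAL" in landmarks:
        verts = _trimmed_vertices(mesh, landmarks)
        untrimmed = False
    else:
        verts = mesh.vertices
        untrimmed = True
    length = float(verts[:, 1].max() - verts[:, 1].min())
    if length <= 0:
        raise GeometryError("bounding box has zero Y extent")
    return length, untrimmed


def truncated_lengths(
    mesh: TriangleMesh, landmarks: LandmarkSet
) -> Tuple[float, float]:
    """Y distances from the bounding-box rear face to MT1 and MT5."""
    landmarks.require("MT1", "MT5")
    if "MED_MAL" in landmarks and "LAT_MAL" in landmarks:
        verts = _trimmed_vertices(mesh, landmarks)
    else:
        verts = mesh.vertices
    y0 = float(verts[:, 1].min())
    l1 = float(landmarks["MT1"][1] - y0)
    l5 = float(landmarks["MT5"][1] - y0)
    if l1 <= 0 or l5 <= 0:
        raise GeometryError("metatarsal landmark lies behind the heel face")
    return l1, l5


def landmark_distances(landmarks: LandmarkSet) -> Tuple[float, float, float]:
    """3-D Euclidean distances (MT1-HEEL, MT1-MT5, MT5-HEEL)."""
    landmarks.require("HEEL", "MT1", "MT5")
    heel, mt1, mt5 = landmarks["HEEL"], landmarks["MT1"], landmarks["MT5"]
    return (
        float(np.linalg.norm(mt1 - heel)),
        float(np.linalg.norm(mt1 - mt5)),
        float(np.linalg.norm(mt5 - heel)),
    )


def _chord_width(trace: PlantarTrace, at_point: np.ndarray) -> float:
    """Length of the X-parallel chord of the trace through ``at_point``."""
    minx, _, maxx, _ = trace.polygon.bounds
    y0 = float(at_point[1])
    line = LineString([(minx - 10.0, y0), (maxx + 10.0, y0)])
    inter = trace.polygon.intersection(line)
    if inter.geom_type in ("MultiLineString", "GeometryCollection"):
        inter = linemerge(
            [g for g in inter.geoms if g.geom_type == "LineString"]
        )
    if inter.is_empty:
        segments = []
    elif inter.geom_type == "LineString":
        segments = [inter]
    elif inter.geom_type == "MultiLineString":
        segments = list(inter.geoms)
    else:
        segments = []
    if not segments:
        raise GeometryError(f"X-parallel chord at y={y0:.2f} misses the trace")
    p = Point(float(at_point[0]), y0)
    best = min(segments, key=lambda s: s.distance(p))
    return float(best.length)


def widths(
    trace: PlantarTrace, landmarks: LandmarkSet
) -> Tuple[float, float, float]:
    """(forefoot_width, midfoot_width, heel_width).

    Forefoot width is the planar distance between the projected MT1/MT5
    points; midfoot and heel widths are trace chords through the projected
    arch and heel points.
    """
    landmarks.require("HEEL", "MT1", "MT5", "ARCH")
    mt1, mt5 = landmarks["MT1"], landmarks["MT5"]
    forefoot = float(np.linalg.norm(mt1[:2] - mt5[:2]))
    midfoot = _chord_width(trace, landmarks["ARCH"])
    heel = _chord_width(trace, landmarks["HEEL"])
    return forefoot, midfoot, heel


def _heel_rear_point(mesh: TriangleMesh, landmarks: LandmarkSet) -> np.ndarray:
    """Rear-most surface point within a narrow X slab at the heel landmark."""
    heel_x = landmarks["HEEL"][0]
    slab = np.abs(mesh.vertices[:, 0] - heel_x) <= _HEEL_SLAB_HALF_WIDTH
    if not slab.any():
        slab = np.ones(len(mesh.vertices), dtype=bool)
    verts = mesh.vertices[slab]
    return verts[np.argmin(verts[:, 1])]


def girths(
    mesh: TriangleMesh, landmarks: LandmarkSet
) -> Tuple[float, float, Optional[float]]:
    """(forefoot_girth, midfoot_girth, hindfoot_girth).

    ``hindfoot_girth`` is ``None`` when the malleoli are absent.
    """
    landmarks.require("HEEL", "MT1", "MT5", "ARCH")
    heel, mt1, mt5 = landmarks["HEEL"], landmarks["MT1"], landmarks["MT5"]
    ez = np.array([0.0, 0.0, 1.0])
    ex = np.array([1.0, 0.0, 0.0])

    # ball girth: vertical plane through MT1 and MT5
    d = mt5 - mt1
    normal = np.cross(d, ez)
    mid_mt = 0.5 * (mt1 + mt5)
    forefoot = cross_section_perimeter(
        mesh, SectionPlane(point=mid_mt, normal=normal, anchor=mid_mt)
    )

    # instep girth: Y-normal plane through midpoint(HEEL, MT1)
    mid_hm = 0.5 * (heel + mt1)
    midfoot = cross_section_perimeter(
        mesh, SectionPlane(point=mid_hm, normal=np.array([0.0, 1.0, 0.0]), anchor=mid_hm)
    )

    hindfoot: Optional[float] = None
    if "MED_MAL" in landmarks:
        rear = _heel_rear_point(mesh, landmarks)
        mid_ma = 0.5 * (landmarks["MED_MAL"] + landmarks["ARCH"])
        u = mid_ma - rear
        normal_h = np.cross(ex, u)
        if np.linalg.norm(normal_h) < 1e-9:
            raise GeometryError("hindfoot girth plane is degenerate")
        anchor = 0.5 * (rear + mid_ma)
        hindfoot = cross_section_perimeter(
            mesh, SectionPlane(point=rear, normal=normal_h, anchor=anchor)
        )
    return forefoot, midfoot, hindfoot


def arch_metrics(
    landmarks: LandmarkSet, heel_to_mt1_length: float
) -> Tuple[float, float]:
    """(arch_height, arch_height_index) from the registered arch point."""
    landmarks.require("ARCH")
    if heel_to_mt1_length <= 0:
        raise GeometryError("truncated foot length must be positive")
    z = float(landmarks["ARCH"][2])
    if z < -1e-9:
        raise GeometryError(f"arch point lies below the plantar plane (z={z:.3g})")
    z = max(z, 0.0)
    return z, z / heel_to_mt1_length


def ankle_angle(landmarks: LandmarkSet) -> float:
    """Angle (degrees) between HEEL->malleoli-midpoint and the +Z vertical."""
    landmarks.require("HEEL", "MED_MAL", "LAT_MAL")
    heel = landmarks["HEEL"]
    mid = 0.5 * (landmarks["MED_MAL"] + landmarks["LAT_MAL"])
    v = mid - heel
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GeometryError("malleoli midpoint coincides with the heel point")
    cosang = np.clip(v[2] / n, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def measure_foot(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    height_cutoff: Optional[float] = None,
    condition: str = "",
) -> MeasurementReport:
    """Register the scene and compute all 15 measurements.

    Requires HEEL, MT1, MT5 and ARCH; without both malleoli the scan is not
    trimmed for foot_length and hindfoot_girth / ankle_angle are left unset
    (flagged in the report).  Sub-operation failures are re-raised as
    :class:`MeasurementError` carrying the measurement name.
    """
    mesh.validate_for_measurement()
    landmarks.require(*("HEEL", "MT1", "MT5", "ARCH"))
    mesh_r, lm_r, _ = register_scene(mesh, landmarks)

    has_malleoli = "MED_MAL" in lm_r and "LAT_MAL" in lm_r
    flags: list[str] = []
    values: dict[str, Optional[float]] = {name: None for name in MEASUREMENT_NAMES}

    def run(name: str, fn):
        try:
            return fn()
        except (GeometryError, MissingLandmarkError) as e:
            raise MeasurementError(name, str(e)) from e

    length, untrimmed = run("foot_length", lambda: foot_length(mesh_r, lm_r))
    values["foot_length"] = length
    if untrimmed:
        flags.append("foot_length:untrimmed")

    l1, l5 = run("heel_to_mt1_length", lambda: truncated_lengths(mesh_r, lm_r))
    values["heel_to_mt1_length"] = l1
    values["heel_to_mt5_length"] = l5

    d1h, d15, d5h = run("dist_mt1_heel", lambda: landmark_distances(lm_r))
    values["dist_mt1_heel"] = d1h
    values["dist_mt1_mt5"] = d15
    values["dist_mt5_heel"] = d5h

    if height_cutoff is None:
        if has_malleoli:
            cutoff = 0.5 * (lm_r["MED_MAL"][2] + lm_r["LAT_MAL"][2])
        else:
            cutoff = DEFAULT_HEIGHT_CUTOFF
            flags.append("trace:default_cutoff")
    else:
        cutoff = height_cutoff
    trace = run("midfoot_width", lambda: plantar_trace(mesh_r, cutoff))

    wf, wm, wh = run("forefoot_width", lambda: widths(trace, lm_r))
    values["forefoot_width"] = wf
    values["midfoot_width"] = wm
    values["heel_width"] = wh

    gf, gm, gh = run("forefoot_girth", lambda: girths(mesh_r, lm_r))
    values["forefoot_girth"] = gf
    values["midfoot_girth"] = gm
    if gh is None:
        flags.append("hindfoot_girth:missing_malleoli")
    else:
        values["hindfoot_girth"] = gh

    ah, ahi = run("arch_height", lambda: arch_metrics(lm_r, l1))
    values["arch_height"] = ah
    values["arch_height_index"] = ahi

    if has_malleoli:
        values["ankle_angle"] = run("ankle_angle", lambda: ankle_angle(lm_r))
    else:
        flags.append("ankle_angle:missing_malleoli")

    return MeasurementReport(
        values=values,
        mesh_name=mesh.name,
        landmark_source=landmarks.source,
        condition=condition,
        flags=tuple(flags),
    )
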
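"""Simple closed test meshes: boxes, cylinders, icospheres, grids.

These primitives back the analytic oracles (known perimeters, areas and
offsets) used throughout the test suite; they are not anatomical models.
"""

from __future__ import annotations

import numpy as np

from .mesh_io import TriangleMesh

__all__ = ["box_mesh", "cylinder_mesh", "icosphere", "grid_mesh"]


def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip all faces if the signed volume is negative (closed meshes only)."""
    tri = vertices[faces]
    vol = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    if vol < 0:
        faces = faces[:, [0, 2, 1]]
    return faces


def box_mesh(extents=(1.0, 1.0, 1.0), center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned box with 8 vertices and 12 outward-facing triangles."""
    e = np.asarray(extents, dtype=np.float64) / 2.0
    c = np.asarray(center, dtype=np.float64)
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=np.float64,
    )
    verts = c + corners * e
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = -e
            [4, 6, 7], [4, 7, 5],  # x = +e
            [0, 4, 5], [0, 5, 1],  # y = -e
            [2, 3, 7], [2, 7, 6],  # y = +e
            [0, 2, 6], [0, 6, 4],  # z = -e
            [1, 5, 7], [1, 7, 3],  # z = +e
        ],
        dtype=np.int64,
    )
    faces = _orient_outward(verts, faces)
    return TriangleMesh(verts, faces, "box")


def cylinder_mesh(
    radius_x: float,
    height: float,
    sections: int = 64,
    radius_y: float | None = None,
    axis: str = "z",
    center=(0.0, 0.0, 0.0),
) -> TriangleMesh:
    """Closed (elliptical) cylinder; ``axis`` in {x, y, z}."""
    ry = radius_x if radius_y is None else radius_y
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    ring = np.column_stack([radius_x * np.cos(theta), ry * np.sin(theta)])
    lo, hi = -height / 2.0, height / 2.0
    bot = np.column_stack([ring, np.full(sections, lo)])
    top = np.column_stack([ring, np.full(sections, hi)])
    cb = np.array([[0.0, 0.0, lo]])
    ct = np.array([[0.0, 0.0, hi]])
    verts = np.vstack([bot, top, cb, ct])
    icb, ict = 2 * sections, 2 * sections + 1

    faces = []
    for i in range(sections):
        j = (i + 1) % sections
        faces.append([i, j, sections + i])
        faces.append([j, sections + j, sections + i])
        faces.append([icb, j, i])
        faces.append([ict, sections + i, sections + j])
    faces = np.asarray(faces, dtype=np.int64)

    perm = {"z": (0, 1, 2), "x": (2, 0, 1), "y": (1, 2, 0)}[axis]
    verts = verts[:, perm] + np.asarray(center, dtype=np.float64)
    faces = _orient_outward(verts, faces)
    return TriangleMesh(verts, faces, "cylinder")


def icosphere(radius: float = 1.0, subdivisions: int = 3, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to the sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = cache.get(key)
            if idx is None:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                idx = len(vlist)
                vlist.append(m)
                cache[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)
    verts = verts * radius + np.asarray(center, dtype=np.float64)
    faces = _orient_outward(verts, faces)
    return TriangleMesh(verts, faces, "icosphere")


def grid_mesh(
    nx: int, ny: int, size_x: float, size_y: float, z: float = 0.0
) -> TriangleMesh:
    """Open rectangular grid in the XY plane with +Z face normals."""
    xs = np.linspace(-size_x / 2, size_x / 2, nx + 1)
    ys = np.linspace(-size_y / 2, size_y / 2, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64), "grid")
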
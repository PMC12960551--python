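"""Low-level mesh geometry kernels: plane sections, point-triangle distances."""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

# offset applied to vertices lying exactly on a cutting plane, in mm
_ON_PLANE_EPS = 1e-9


def plane_section_loops(
    vertices: np.ndarray,
    faces: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
) -> List[Tuple[np.ndarray, bool]]:
    """Intersect a triangle mesh with a plane.

    Returns a list of ``(points, closed)`` polylines; points are ordered along
    the polyline. Closed loops do not repeat the first point.
    """
    normal = np.asarray(normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    d = (vertices - np.asarray(point, dtype=np.float64)) @ normal
    d = np.where(d == 0.0, _ON_PLANE_EPS, d)

    fd = d[faces]  # (m, 3)
    pos = fd > 0
    cut = pos.any(axis=1) & (~pos).any(axis=1)
    if not cut.any():
        return []

    cut_faces = faces[cut]
    cut_fd = fd[cut]

    # for each cut face, find its two crossed edges (sign change along edge)
    edge_pairs = ((0, 1), (1, 2), (2, 0))
    pt_index: dict[tuple[int, int], int] = {}
    pts: list[np.ndarray] = []
    links: list[tuple[int, int]] = []
    for f, dv in zip(cut_faces, cut_fd):
        nodes = []
        for a, b in edge_pairs:
            da, db = dv[a], dv[b]
            if (da > 0) == (db > 0):
                continue
            i, j = int(f[a]), int(f[b])
            key = (i, j) if i < j else (j, i)
            idx = pt_index.get(key)
            if idx is None:
                t = da / (da - db)
                p = vertices[i] + t * (vertices[j] - vertices[i])
                idx = len(pts)
                pts.append(p)
                pt_index[key] = idx
            nodes.append(idx)
        if len(nodes) == 2:
            links.append((nodes[0], nodes[1]))

    # chain links into polylines / loops
    adjacency: dict[int, list[int]] = {}
    for li, (a, b) in enumerate(links):
        adjacency.setdefault(a, []).append(li)
        adjacency.setdefault(b, []).append(li)

    used = [False] * len(links)
    out: List[Tuple[np.ndarray, bool]] = []
    for start_link in range(len(links)):
        if used[start_link]:
            continue
        a, b = links[start_link]
        used[start_link] = True
        chain = [a, b]
        # extend forward from b, then (if open) backward from a
        for _ in range(2):
            while True:
                tail = chain[-1]
                nxt = None
                for li in adjacency.get(tail, ()):  # pick any unused link at tail
                    if not used[li]:
                        nxt = li
                        break
                if nxt is None:
                    break
                used[nxt] = True
                u, v = links[nxt]
                chain.append(v if u == tail else u)
                if chain[-1] == chain[0]:
                    break
            if chain[-1] == chain[0]:
                break
            chain.reverse()
        closed = chain[0] == chain[-1]
        if closed:
            chain = chain[:-1]
        out.append((np.asarray([pts[i] for i in chain]), closed))
    return out


def polyline_length(points: np.ndarray, closed: bool) -> float:
    seg = np.diff(points, axis=0)
    total = float(np.linalg.norm(seg, axis=1).sum())
    if closed:
        total += float(np.linalg.norm(points[0] - points[-1]))
    return total


def closest_point_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest points on triangles (a, b, c) to query points p (broadcasting).

    Vectorised version of the classic region-based algorithm.
    Shapes: p (..., 3) against triangles (..., 3); output (..., 3).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w_in = np.where(denom != 0, vc / denom, 1.0 / 3.0)

    cand_a = np.broadcast_to(a, np.broadcast_shapes(p.shape, a.shape))
    cand_b = np.broadcast_to(b, cand_a.shape)
    cand_c = np.broadcast_to(c, cand_a.shape)
    cand_ab = a + v_ab[..., None] * ab
    cand_ac = a + w_ac[..., None] * ac
    cand_bc = b + w_bc[..., None] * (c - b)
    cand_in = a + v_in[..., None] * ab + w_in[..., None] * ac

    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    m_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

    out = cand_in.copy()
    for mask, cand in (
        (m_bc, cand_bc),
        (m_ac, cand_ac),
        (m_ab, cand_ab),
        (m_c, cand_c),
        (m_b, cand_b),
        (m_a, cand_a),
    ):
        out = np.where(mask[..., None], cand, out)
    return out


def signed_distance_to_mesh(
    points: np.ndarray,
    ref_vertices: np.ndarray,
    ref_faces: np.ndarray,
    k_candidates: int = 24,
) -> np.ndarray:
    """Signed distance from points to a mesh surface.

    Sign is taken from the nearest face's normal (positive = outside along the
    normal). Degenerate reference faces are ignored.

    Candidate faces are pre-filtered with KD-trees: the distance to the
    nearest reference vertex bounds the true surface distance from above, so
    every face that could be closer has its centroid within that bound plus
    the largest face circumradius. Points whose k nearest centroids do not
    certainly cover that ball fall back to an exact ball query.
    """
    from scipy.spatial import cKDTree

    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    tri = ref_vertices[ref_faces]
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lens = np.linalg.norm(nrm, axis=1)
    ok = lens > 1e-12
    tri = tri[ok]
    nrm = nrm[ok] / lens[ok, None]
    m = len(tri)
    if m == 0:
        raise ValueError("reference mesh has no non-degenerate faces")

    centroids = tri.mean(axis=1)
    r_face = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    r_max = float(r_face.max())

    vtree = cKDTree(ref_vertices)
    ctree = cKDTree(centroids)
    d_up = vtree.query(points)[0]  # upper bound on the surface distance

    k = min(k_candidates, m)
    dc, idx = ctree.query(points, k=k)
    if k == 1:
        dc = dc[:, None]
        idx = idx[:, None]

    cand_tri = tri[idx]  # (q, k, 3, 3)
    cp = closest_point_on_triangles(
        points[:, None, :], cand_tri[:, :, 0], cand_tri[:, :, 1], cand_tri[:, :, 2]
    )
    diff = points[:, None, :] - cp
    d2 = np.sum(diff * diff, axis=-1)
    j = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    dist = np.sqrt(d2[rows, j])
    face_j = idx[rows, j]
    sgn = np.sign(np.sum(diff[rows, j] * nrm[face_j], axis=-1))
    sgn[sgn == 0] = 1.0
    out = sgn * dist

    # exact fallback where the k-nearest centroids may not cover the bound
    unsafe = (k < m) & (dc[:, -1] < d_up + r_max)
    if np.isscalar(unsafe):
        unsafe = np.full(len(points), unsafe)
    for i in np.nonzero(unsafe)[0]:
        cand = ctree.query_ball_point(points[i], d_up[i] + r_max + 1e-9)
        if not cand:
            continue
        ct = tri[cand]
        cpi = closest_point_on_triangles(
            points[i][None, :], ct[:, 0], ct[:, 1], ct[:, 2]
        )
        di = points[i][None, :] - cpi
        d2i = np.sum(di * di, axis=-1)
        ji = int(np.argmin(d2i))
        si = np.sign(float(np.dot(di[ji], nrm[cand[ji]]))) or 1.0
        out[i] = si * np.sqrt(d2i[ji])
    return out
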
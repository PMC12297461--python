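"""Brute-force reference implementations used only as test oracles.

The polytope clipper here is deliberately independent of the package's
geometry path: cells are represented as explicit face polygons and clipped
one bisector plane at a time (Sutherland–Hodgman in 3D); volumes and
centroids come from a tetrahedral fan.  Slow (O(n) planes per cell) but
transparent.
"""
from __future__ import annotations

import numpy as np

_PHI = (1.0 + 5.0 ** 0.5) / 2.0


def dodecahedron_faces(edge_length: float, centre) -> list:
    """Regular dodecahedron as 12 ordered face polygons."""
    inv = 1.0 / _PHI
    verts = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                verts.append((sx, sy, sz))
    for a, b in ((inv, _PHI), (-inv, _PHI), (inv, -_PHI), (-inv, -_PHI)):
        verts.append((0.0, a, b))
        verts.append((a, b, 0.0))
        verts.append((b, 0.0, a))
    verts = np.asarray(verts) * (edge_length * _PHI / 2.0)

    # recover the 12 pentagonal faces by grouping hull facet normals
    from scipy.spatial import ConvexHull

    hull = ConvexHull(verts)
    seen = []
    faces = []
    centre = np.asarray(centre, dtype=float)
    for eq in hull.equations:
        d, support = eq[:3], -eq[3]
        if any(np.allclose(d, s, atol=1e-6) for s in seen):
            continue
        seen.append(d)
        dots = verts @ d
        members = verts[dots > support - 1e-6 * max(edge_length, 1.0)]
        assert len(members) == 5
        faces.append(("solid", _order_polygon(members + centre, d)))
    assert len(faces) == 12
    return faces


def _order_polygon(pts: np.ndarray, normal: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    ang = np.arctan2((pts - c) @ e2, (pts - c) @ e1)
    return pts[np.argsort(ang)]


def clip_polytope(faces: list, tag, normal, offset, tol=1e-9):
    """Clip face-represented convex polytope by half-space n·x <= offset."""
    normal = np.asarray(normal, dtype=float)
    new_faces = []
    section = []
    for label, poly in faces:
        kept = []
        m = len(poly)
        d = poly @ normal - offset
        for i in range(m):
            a, b = poly[i], poly[(i + 1) % m]
            da, db = d[i], d[(i + 1) % m]
            if da <= tol:
                kept.append(a)
            if (da < -tol and db > tol) or (da > tol and db < -tol):
                t = da / (da - db)
                p = a + t * (b - a)
                kept.append(p)
                section.append(p)
        if len(kept) >= 3:
            new_faces.append((label, np.asarray(kept)))
    if len(section) >= 3:
        sec = np.asarray(section)
        # deduplicate
        uniq = [sec[0]]
        for p in sec[1:]:
            if min(np.linalg.norm(p - q) for q in uniq) > 1e-9:
                uniq.append(p)
        if len(uniq) >= 3:
            new_faces.append((tag, _order_polygon(np.asarray(uniq), normal)))
    return new_faces


def polytope_volume_centroid(faces: list):
    verts = np.vstack([poly for _, poly in faces])
    ref = verts.mean(axis=0)
    vol = 0.0
    cent = np.zeros(3)
    for _, poly in faces:
        for i in range(1, len(poly) - 1):
            a, b, c = poly[0] - ref, poly[i] - ref, poly[i + 1] - ref
            v = abs(np.dot(a, np.cross(b, c))) / 6.0
            vol += v
            cent += v * (ref + poly[0] + poly[i] + poly[i + 1]) / 4.0
    return vol, cent / vol


def polygon_area(poly: np.ndarray) -> float:
    c = poly.mean(axis=0)
    s = np.zeros(3)
    for i in range(len(poly)):
        s += np.cross(poly[i] - c, poly[(i + 1) % len(poly)] - c)
    return 0.5 * np.linalg.norm(s)


def restricted_voronoi_oracle(points: np.ndarray, edge_length: float,
                              face_area_min: float = 1e-9):
    """Clip every seed's dodecahedron by all n-1 bisector planes.

    Returns (volumes, centroids, neighbour sets, n_solid_faces) with the
    mutual-face adjacency rule applied.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    volumes = np.empty(n)
    centroids = np.empty((n, 3))
    raw_nb = []
    n_solid = np.zeros(n, dtype=int)
    for i in range(n):
        faces = dodecahedron_faces(edge_length, pts[i])
        for j in range(n):
            if j == i:
                continue
            diff = pts[j] - pts[i]
            dist = np.linalg.norm(diff)
            u = diff / dist
            faces = clip_polytope(faces, j, u, u @ pts[i] + dist / 2.0)
        volumes[i], centroids[i] = polytope_volume_centroid(faces)
        nb = set()
        for label, poly in faces:
            if polygon_area(poly) < face_area_min:
                continue
            if label == "solid":
                n_solid[i] += 1
            else:
                nb.add(label)
        raw_nb.append(nb)
    neighbours = [set(j for j in raw_nb[i] if i in raw_nb[j])
                  for i in range(n)]
    return volumes, centroids, neighbours, n_solid
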
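"""Adaptively restricted 3D Voronoi tessellations.

A conventional Voronoi diagram assigns unbounded cells to points on the
convex hull of a cloud, which makes boundary tissues (e.g. the skin of an
embryo) unusable.  Here every cell is initialised as a regular dodecahedron
of configurable edge length centred on its seed and cropped by the
perpendicular-bisector half-spaces of the surrounding seeds, so cells can
never exceed the bounding solid.  Cells that retain at least one face of
their initial dodecahedron are *boundary* cells.  A second, adaptive pass
closes boundary cells at the scale of their local neighbourhood by adding
auxiliary points — each boundary seed's face neighbours mirrored through the
seed — and re-tessellating, which smoothly extends every local neighbourhood
by one artificial cell layer.

Cells are convex polyhedra; per-cell volume, centroid, the face-sharing
(Delaunay) neighbour graph and boundary flags are exposed through
:class:`Tessellation`.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection, Voronoi, cKDTree

logger = logging.getLogger(__name__)

PHI = (1.0 + np.sqrt(5.0)) / 2.0
#: volume of a regular dodecahedron with unit edge length
DODECAHEDRON_VOLUME_FACTOR = (15.0 + 7.0 * np.sqrt(5.0)) / 4.0

_FACE_AREA_MIN = 1e-9  # µm^2; smaller faces are numerical slivers
_COINCIDENT_TOL = 1e-9  # µm; closer seed pairs are a degeneracy
_JIGGLE_REL = 1e-9  # symbolic perturbation, relative to median NN spacing
_JIGGLE_SEED = 721_831  # fixed: tessellation stays deterministic
_ONPLANE_TOL = 1e-6  # µm; vertex-to-plane distance that counts as "on face"
_COVERAGE_RATIO = 1.5  # a cell is "extended" when some vertex lies further
# than this multiple of the local spacing from EVERY seed: its geometry
# reaches outside the cloud (boundary wedges that self-cage without
# retaining a bounding-solid face)


class DegeneracyError(ValueError):
    """Raised when seeds coincide (within 1e-9 µm) or geometry degenerates."""


@dataclass
class BoundedCell:
    """One restricted Voronoi cell (view onto a :class:`Tessellation`)."""

    seed_index: int
    volume: float
    centroid: np.ndarray
    face_neighbours: np.ndarray
    n_unshared_faces: int
    n_aux_faces: int
    is_boundary: bool


@dataclass
class Tessellation:
    """Restricted Voronoi diagram over one point cloud.

    Arrays are aligned to the input point order; auxiliary points used for
    boundary closure are stored separately and never appear as cells.
    """

    points: np.ndarray
    volumes: np.ndarray
    centroids: np.ndarray
    neighbours: list  # list of int arrays, real-seed face neighbours
    n_unshared_faces: np.ndarray
    n_aux_faces: np.ndarray
    is_boundary: np.ndarray
    bounding_edge_length: float
    vertex_radius: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_extended: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    cell_vertices: list = field(default_factory=list)
    auxiliary_points: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3)))

    def __len__(self):
        return len(self.volumes)

    def cell(self, i: int) -> BoundedCell:
        return BoundedCell(
            seed_index=i,
            volume=float(self.volumes[i]),
            centroid=self.centroids[i],
            face_neighbours=self.neighbours[i],
            n_unshared_faces=int(self.n_unshared_faces[i]),
            n_aux_faces=int(self.n_aux_faces[i]),
            is_boundary=bool(self.is_boundary[i]),
        )

    @property
    def cells(self) -> list:
        return [self.cell(i) for i in range(len(self))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "volume": self.volumes,
            "centroid_x": self.centroids[:, 0],
            "centroid_y": self.centroids[:, 1],
            "centroid_z": self.centroids[:, 2],
            "n_neighbours": [len(nb) for nb in self.neighbours],
            "is_boundary": self.is_boundary,
        })

    def edges_to_frame(self):
        """Face-sharing edge list (i < j) with seed distances in µm."""
        import pandas as pd

        rows = []
        for i, nb in enumerate(self.neighbours):
            for j in nb:
                if i < j:
                    rows.append((i, int(j), float(np.linalg.norm(
                        self.points[i] - self.points[j]))))
        return pd.DataFrame(rows, columns=["i", "j", "distance_um"])


# ---------------------------------------------------------------------------
# bounding solid


def dodecahedron_vertices(edge_length: float) -> np.ndarray:
    """Vertices of a regular dodecahedron, canonical orientation, origin centre."""
    inv = 1.0 / PHI
    v = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                v.append((sx, sy, sz))
    for a, b in ((inv, PHI), (-inv, PHI), (inv, -PHI), (-inv, -PHI)):
        v.append((0.0, a, b))
        v.append((a, b, 0.0))
        v.append((b, 0.0, a))
    v = np.asarray(v, dtype=float)
    # raw edge length is 2/phi
    return v * (edge_length * PHI / 2.0)


def _unit_dodecahedron_planes():
    """Unique face planes of the unit-edge solid, from its convex hull."""
    hull = ConvexHull(dodecahedron_vertices(1.0))
    # qhull triangulates: average the (near-identical) equations per face
    keys = np.round(hull.equations, 6)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    groups = [hull.equations[inverse == g].mean(axis=0)
              for g in range(inverse.max() + 1)]
    eq = np.asarray(groups)
    assert len(eq) == 12
    norms = np.linalg.norm(eq[:, :3], axis=1)
    return eq[:, :3] / norms[:, None], -eq[:, 3] / norms


_UNIT_NORMALS, _UNIT_SUPPORT = _unit_dodecahedron_planes()


def dodecahedron_halfspaces(edge_length: float):
    """(unit normals (12,3), support distances (12,)) of the bounding solid."""
    return _UNIT_NORMALS.copy(), _UNIT_SUPPORT * edge_length


def dodecahedron_volume(edge_length: float) -> float:
    return DODECAHEDRON_VOLUME_FACTOR * edge_length ** 3


def circumradius(edge_length: float) -> float:
    return np.sqrt(3.0) * edge_length * PHI / 2.0


# ---------------------------------------------------------------------------
# polyhedron helpers


def _hull_volume_centroid(vertices: np.ndarray):
    hull = ConvexHull(vertices)
    ref = vertices.mean(axis=0)
    simplices = vertices[hull.simplices]  # (m, 3, 3)
    a = simplices[:, 0] - ref
    b = simplices[:, 1] - ref
    c = simplices[:, 2] - ref
    vols = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    cents = (ref + simplices.sum(axis=1)) / 4.0
    total = vols.sum()
    centroid = (cents * vols[:, None]).sum(axis=0) / total
    return float(hull.volume), centroid


def _polygon_area(pts: np.ndarray, normal: np.ndarray) -> float:
    """Area of a planar convex polygon given unordered vertices."""
    centre = pts.mean(axis=0)
    # orthonormal basis in the plane
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = pts - centre
    u = rel @ e1
    v = rel @ e2
    order = np.argsort(np.arctan2(v, u))
    u, v = u[order], v[order]
    return 0.5 * abs(np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1)))


def _ridge_face_mask(vor, jiggle_eps: float) -> np.ndarray:
    """Vectorised sliver filter over all Voronoi ridges.

    A ridge polygon with base ``diam`` and height ``width`` has area between
    diam*width/2 and diam*width, so testing the width against the sliver
    scale is equivalent (within 2x) to the area test of :func:`_face_ok`.
    Unbounded ridges are passed through (their cells take the slow path,
    which applies the exact face test).
    """
    ridges = vor.ridge_vertices
    nr = len(ridges)
    keep = np.ones(nr, dtype=bool)
    lens = np.fromiter((len(rv) for rv in ridges), dtype=int, count=nr)
    bounded = np.fromiter((-1 not in rv for rv in ridges), dtype=bool,
                          count=nr)
    check = bounded & (lens >= 3)
    if not check.any():
        keep[bounded & (lens < 3)] = False
        return keep
    rows = np.nonzero(check)[0]
    maxlen = lens[rows].max()
    idx = np.zeros((len(rows), maxlen), dtype=int)
    mask = np.zeros((len(rows), maxlen), dtype=bool)
    for r, row in enumerate(rows):
        rv = ridges[row]
        idx[r, :len(rv)] = rv
        mask[r, :len(rv)] = True
    V = vor.vertices[idx]  # (R, L, 3)
    rel = V - V[:, :1]
    rel[~mask] = 0.0
    d2 = np.einsum("rlk,rlk->rl", rel, rel)
    k = d2.argmax(axis=1)
    diam = np.sqrt(d2[np.arange(len(rows)), k])
    safe = np.where(diam > 0, diam, 1.0)
    axis = rel[np.arange(len(rows)), k] / safe[:, None]
    proj = np.einsum("rlk,rk->rl", rel, axis)
    perp2 = np.maximum(d2 - proj ** 2, 0.0)
    width = np.sqrt(perp2.max(axis=1))
    w_min = np.maximum(2.0 * _FACE_AREA_MIN / np.maximum(diam, 1e-12),
                       20.0 * jiggle_eps)
    keep[rows] = (diam > 0) & (width >= w_min)
    keep[bounded & (lens < 3)] = False
    return keep


# ---------------------------------------------------------------------------
# per-cell clipping (slow path)


def _clip_cell(i, seeds, tree, dod_normals, dod_support, edge_length,
               jiggle_eps=0.0, extra_normals=None, extra_offsets=None):
    """Clip seed i's dodecahedron by bisector half-spaces of nearby seeds.

    Candidate bisectors are discovered iteratively: only seeds within twice
    the current maximum vertex distance can still cut the cell (the security
    radius used by incremental Voronoi codes).
    """
    x = seeds[i]
    n = len(seeds)
    r_circ = circumradius(edge_length)

    used: list[int] = []
    k0 = min(n - 1, 32)
    if k0 > 0:
        _, idx = tree.query(x, k=k0 + 1)
        used = [j for j in np.atleast_1d(idx) if j != i][:k0]

    vertices = None
    for _ in range(64):  # converges in a handful of rounds
        normals = [dod_normals]
        offsets = [dod_normals @ x + dod_support]
        if extra_normals is not None:
            normals.append(extra_normals)
            offsets.append(extra_offsets)
        if used:
            diff = seeds[used] - x
            dist = np.linalg.norm(diff, axis=1)
            u = diff / dist[:, None]
            normals.append(u)
            offsets.append(u @ x + dist / 2.0)
        normals_all = np.vstack(normals)
        offsets_all = np.concatenate(offsets)
        hs = np.column_stack([normals_all, -offsets_all])
        try:
            hsi = HalfspaceIntersection(hs, x)
        except Exception as exc:  # qhull degeneracy
            raise DegeneracyError(
                f"half-space intersection failed for seed {i}: {exc}") from exc
        vertices = hsi.intersections
        m = np.linalg.norm(vertices - x, axis=1).max()
        radius = min(2.0 * m * (1.0 + 1e-9), 2.0 * r_circ)
        cand = tree.query_ball_point(x, radius)
        known = set(used)
        known.add(i)
        cand = [j for j in cand if j not in known]
        if not cand:
            break
        diff = seeds[cand] - x
        dist = np.linalg.norm(diff, axis=1)
        u = diff / dist[:, None]
        # a bisector cuts the cell iff some vertex lies beyond it
        proj = u @ (vertices - x).T  # (n_cand, n_vert)
        cuts = proj.max(axis=1) > dist / 2.0 - 1e-9
        new = [c for c, f in zip(cand, cuts) if f]
        if not new:
            break
        used.extend(new)

    volume, centroid = _hull_volume_centroid(vertices)
    vertex_radius = float(np.linalg.norm(vertices - x, axis=1).max())

    # identify which half-spaces carry actual faces
    slack = normals_all @ vertices.T - offsets_all[:, None]
    onplane = np.abs(slack) < _ONPLANE_TOL
    n_dod = 12
    n_extra = 0 if extra_normals is None else len(extra_normals)
    neighbours = []
    n_unshared = 0
    for h in range(len(normals_all)):
        vid = np.nonzero(onplane[h])[0]
        if len(vid) < 3:
            continue
        if not _face_ok(vertices[vid], normals_all[h], jiggle_eps):
            continue
        if h < n_dod + n_extra:
            n_unshared += 1
        else:
            neighbours.append(used[h - n_dod - n_extra])
    return (volume, centroid, np.asarray(neighbours, dtype=int), n_unshared,
            vertex_radius, vertices)


# ---------------------------------------------------------------------------
# main driver


def _validate_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point set")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        bad = np.nonzero(~np.isfinite(pts).all(axis=1))[0]
        raise ValueError(f"non-finite coordinates at rows {bad.tolist()}")
    if len(pts) > 1:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(_COINCIDENT_TOL)
        if pairs:
            raise DegeneracyError(
                f"coincident points (within {_COINCIDENT_TOL} µm): "
                f"{sorted(pairs)[:10]}")
    return pts


def _jiggle(pts: np.ndarray, n_real=None):
    """Deterministic symbolic perturbation to break cospherical ties.

    Returns the perturbed points and the perturbation amplitude (µm), which
    downstream face filters use to recognise degeneracy slivers.  The
    amplitude derives from the first ``n_real`` (non-auxiliary) points so
    that both tessellation passes perturb the real seeds identically.
    """
    if len(pts) < 2:
        return pts, 0.0
    base = pts if n_real is None or n_real < 2 else pts[:n_real]
    tree = cKDTree(base)
    d, _ = tree.query(base, k=2)
    spacing = float(np.median(d[:, 1]))
    eps = _JIGGLE_REL * spacing
    rng = np.random.default_rng(_JIGGLE_SEED)
    return pts + rng.uniform(-1.0, 1.0, pts.shape) * eps, eps


def _face_ok(verts: np.ndarray, normal: np.ndarray, jiggle_eps: float) -> bool:
    """True if a candidate face polygon is a genuine face, not a sliver.

    Slivers produced by the symbolic perturbation have width of order the
    jiggle amplitude, hence area ~ amplitude x diameter; the threshold
    scales accordingly (with the absolute 1e-9 µm^2 floor).
    """
    if len(verts) < 3:
        return False
    diam = float(np.linalg.norm(verts.max(axis=0) - verts.min(axis=0)))
    area = _polygon_area(verts, normal)
    return area >= max(_FACE_AREA_MIN, 10.0 * jiggle_eps * diam)


def _tessellate(seeds: np.ndarray, n_real: int, edge_length: float,
                container_halfspaces=None) -> Tessellation:
    """Restricted Voronoi over `seeds`; cells emitted for the first n_real."""
    t0 = time.perf_counter()
    pts, jiggle_eps = _jiggle(seeds, n_real)
    n = len(pts)
    tree = cKDTree(pts)
    dod_normals, dod_support = dodecahedron_halfspaces(edge_length)
    r_in = dod_support[0]
    extra_n = extra_o = None
    if container_halfspaces is not None:
        extra_n = np.asarray(container_halfspaces[0], dtype=float)
        extra_o = np.asarray(container_halfspaces[1], dtype=float)

    volumes = np.empty(n_real)
    centroids = np.empty((n_real, 3))
    raw_neighbours: list = [None] * n_real
    n_unshared = np.zeros(n_real, dtype=int)
    vertex_radius = np.empty(n_real)
    cell_vertices: list = [None] * n_real

    slow = list(range(n_real))
    if n >= 5 and container_halfspaces is None:
        # fast path: cells of the unrestricted Voronoi diagram that lie
        # strictly inside their bounding dodecahedron are unaffected by it
        vor = Voronoi(pts)
        keep = _ridge_face_mask(vor, jiggle_eps)
        ridge_nb: list = [[] for _ in range(n)]
        for (p, q), ok in zip(vor.ridge_points, keep):
            if ok:
                ridge_nb[p].append(q)
                ridge_nb[q].append(p)
        slow = []
        for i in range(n_real):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) < 4:
                slow.append(i)
                continue
            verts = vor.vertices[region]
            if (dod_normals @ (verts - pts[i]).T).max() >= r_in - 1e-9:
                slow.append(i)
                continue
            volume, centroid = _hull_volume_centroid(verts)
            volumes[i] = volume
            centroids[i] = centroid
            raw_neighbours[i] = np.asarray(ridge_nb[i], dtype=int)
            n_unshared[i] = 0
            vertex_radius[i] = np.linalg.norm(verts - pts[i], axis=1).max()
            cell_vertices[i] = verts

    for i in slow:
        volume, centroid, nb, nu, vr, verts = _clip_cell(
            i, pts, tree, dod_normals, dod_support, edge_length,
            jiggle_eps, extra_n, extra_o)
        volumes[i] = volume
        centroids[i] = centroid
        raw_neighbours[i] = nb
        n_unshared[i] = nu
        vertex_radius[i] = vr
        cell_vertices[i] = verts

    # symmetrise adjacency (mutual face detection) and split real/aux
    nb_sets = [set(np.asarray(nb).tolist()) for nb in raw_neighbours]
    neighbours = []
    n_aux = np.zeros(n_real, dtype=int)
    for i in range(n_real):
        real = []
        aux = 0
        for j in nb_sets[i]:
            if j >= n_real:
                aux += 1
            elif i in nb_sets[j]:
                real.append(j)
        n_aux[i] = aux
        neighbours.append(np.asarray(sorted(real), dtype=int))

    is_boundary = (n_unshared > 0) | (n_aux > 0)
    # cells with vertices that no seed covers are flagged "extended":
    # morphological boundary wedges even without retained solid faces
    local = np.array([
        np.median(np.linalg.norm(seeds[nb] - seeds[i], axis=1))
        if len(nb) else 0.0
        for i, nb in enumerate(neighbours)])
    is_extended = np.ones(n_real, dtype=bool)
    seed_tree = cKDTree(seeds)
    for i in range(n_real):
        if local[i] <= 0 or cell_vertices[i] is None:
            continue
        d, _ = seed_tree.query(cell_vertices[i])
        is_extended[i] = bool(d.max() > _COVERAGE_RATIO * local[i])
    logger.info("tessellated %d cells (%d slow-path) in %.2fs",
                n_real, len(slow), time.perf_counter() - t0)
    return Tessellation(
        points=np.asarray(seeds[:n_real], dtype=float),
        volumes=volumes,
        centroids=centroids,
        neighbours=neighbours,
        n_unshared_faces=n_unshared,
        n_aux_faces=n_aux,
        is_boundary=is_boundary,
        bounding_edge_length=edge_length,
        vertex_radius=vertex_radius,
        is_extended=is_extended.astype(bool),
        cell_vertices=cell_vertices,
        auxiliary_points=np.asarray(seeds[n_real:], dtype=float),
    )


def restricted_voronoi(points, edge_length: float = 100.0,
                       container_halfspaces=None) -> Tessellation:
    """First-pass restricted Voronoi diagram.

    Each cell is the intersection of a regular dodecahedron (edge
    ``edge_length``, canonical orientation) centred on its seed with the
    perpendicular-bisector half-spaces of all other seeds.  Cells that keep
    at least one dodecahedron face are flagged as boundary cells.

    Parameters
    ----------
    points : (n, 3) array
        Nuclear centroids in µm.
    edge_length : float
        Edge length of the bounding dodecahedron, µm.
    container_halfspaces : (normals, offsets), optional
        Additional world-frame clip planes ``n·x <= o`` applied to every
        cell (e.g. the faces of a known container).
    """
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    pts = _validate_points(points)
    return _tessellate(pts, len(pts), edge_length, container_halfspaces)


def generate_auxiliary_points(tessellation: Tessellation,
                              points=None) -> np.ndarray:
    """Mirror each boundary cell's face neighbours through the boundary seed.

    For boundary cell i with face neighbour j the reflection ``2·x_i − x_j``
    is emitted; duplicates (within 1e-6 µm) are merged and reflections that
    land within 1e-3 µm of a real nucleus are dropped.  Returns an (m, 3)
    array (possibly empty).
    """
    pts = tessellation.points if points is None else np.asarray(points, float)
    emitters = tessellation.is_boundary
    if len(tessellation.is_extended):
        emitters = emitters | tessellation.is_extended
    out = []
    for i in np.nonzero(emitters)[0]:
        nb = tessellation.neighbours[i]
        if len(nb):
            out.append(2.0 * pts[i] - pts[nb])
    if not out:
        return np.empty((0, 3))
    cand = np.vstack(out)
    # deduplicate within 1e-6 µm
    tree = cKDTree(cand)
    keep = np.ones(len(cand), dtype=bool)
    for a, b in tree.query_pairs(1e-6):
        if keep[a] and keep[b]:
            keep[max(a, b)] = False
    cand = cand[keep]
    # drop reflections colliding with real nuclei
    real = cKDTree(pts)
    d, _ = real.query(cand, k=1)
    cand = cand[d > 1e-3]
    # drop reflections that would cut a *local* interior cell (a new seed
    # cuts cell k iff some vertex of k is closer to it than to k's own
    # seed); this keeps locally-determined interior geometry exactly
    # invariant under the second pass, while extended boundary wedges stay
    # cuttable so that the closure can cap them
    interior = np.nonzero(~tessellation.is_boundary
                          & ~tessellation.is_extended)[0]
    if len(interior) and len(cand) and tessellation.cell_vertices:
        vr = tessellation.vertex_radius[interior]
        ctree = cKDTree(cand)
        keep = np.ones(len(cand), dtype=bool)
        hits = ctree.query_ball_point(pts[interior], 2.0 * vr)
        for h, cidx in enumerate(hits):
            cidx = [c for c in cidx if keep[c]]
            if not cidx:
                continue
            k = interior[h]
            verts = tessellation.cell_vertices[k]
            d_seed = np.linalg.norm(verts - pts[k], axis=1)
            diff = cand[cidx][:, None, :] - verts[None, :, :]
            d_new = np.sqrt(np.einsum("hvk,hvk->hv", diff, diff))
            cuts = (d_new < d_seed[None, :] - 1e-9).any(axis=1)
            keep[np.asarray(cidx)[cuts]] = False
        cand = cand[keep]
    return cand


def adaptive_voronoi(points, edge_length: float = 100.0) -> Tessellation:
    """Two-pass adaptively restricted Voronoi diagram.

    The first pass flags boundary cells; auxiliary points (one mirrored cell
    layer) are generated and a second tessellation over the union closes
    boundary cells at the scale of their local neighbourhood.  Cells are
    reported for the real points only; interior cells are unchanged between
    passes and boundary-cell volumes can only shrink.
    """
    pts = _validate_points(points)
    first = _tessellate(pts, len(pts), edge_length)
    aux = generate_auxiliary_points(first, pts)
    if len(aux) == 0:
        return first
    seeds = np.vstack([pts, aux])
    return _tessellate(seeds, len(pts), edge_length)


def adjacency(tessellation: Tessellation):
    """Face-sharing neighbour lists plus pairwise seed distances (µm).

    Returns ``(neighbours, distances)``: aligned lists of int / float arrays
    over real nuclei only.  Counts of auxiliary-facing faces stay available
    on the tessellation (``n_aux_faces``).
    """
    pts = tessellation.points
    dists = [np.linalg.norm(pts[nb] - pts[i], axis=1)
             for i, nb in enumerate(tessellation.neighbours)]
    return tessellation.neighbours, dists
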
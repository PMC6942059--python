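"""Low-level geometry kernels shared across the package.

Everything here operates on plain numpy arrays or :class:`trimesh.Trimesh`
objects in millimetres.  The three non-trivial kernels are:

* polygon ear-clipping triangulation (used to cap planar cuts and to build
  extrusion prisms without an external triangulation engine);
* the *vertical-prism volume integral*: the volume of a watertight mesh
  intersected with ``{(x,z) in P} x {y_min <= y <= y_max}`` computed exactly
  from the divergence theorem with per-triangle 2D clipping.  Because the
  prism walls are vertical they carry zero flux of the field ``(0, y, 0)``,
  so no boolean mesh operation is ever required;
* a column (ray-parity) voxelizer used both as an independent brute-force
  volume oracle and to build occupancy grids for acquisition emulation.
"""

from __future__ import annotations

import numpy as np
import shapely
import trimesh
from scipy.spatial import cKDTree
from shapely.geometry import MultiPolygon, Polygon
from shapely.strtree import STRtree

# vertices closer than this (mm) are considered coincident
MERGE_TOL = 1e-6
# triangles with |integral of n_y dA| below this are treated as vertical
VERTICAL_TOL = 1e-9


class GeometryError(RuntimeError):
    """Raised when a geometric operation cannot produce a valid result."""


# ---------------------------------------------------------------------------
# basic mesh helpers
# ---------------------------------------------------------------------------

def as_mesh(vertices, faces) -> trimesh.Trimesh:
    """Build a Trimesh without any automatic processing/reordering."""
    return trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )


def merge_close_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = MERGE_TOL
):
    """Union-find merge of vertices closer than ``tol``.

    Unlike grid-rounding merges this cannot be defeated by a pair that
    straddles a rounding bucket.  Faces collapsing to fewer than three
    distinct vertices are dropped.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(vertices))

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(len(vertices))])
    uniq, remap = np.unique(roots, return_inverse=True)
    new_verts = vertices[uniq]
    new_faces = remap[faces]
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 2] != new_faces[:, 0])
    )
    return new_verts, new_faces[ok]


def signed_volume(mesh: trimesh.Trimesh) -> float:
    """Signed volume via the divergence theorem (positive for outward winding)."""
    tri = mesh.triangles
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def volume_yflux(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Volume from the flux of ``(0, y, 0)``; tolerant of T-junction soups.

    Vertical faces carry no flux, so meshes whose vertical walls are only
    approximately stitched still integrate exactly.
    """
    tri = np.asarray(vertices, dtype=float)[np.asarray(faces)]
    # integral of n_y dA over a triangle equals minus its signed (x,z) area
    a2 = 0.5 * (
        (tri[:, 1, 0] - tri[:, 0, 0]) * (tri[:, 2, 2] - tri[:, 0, 2])
        - (tri[:, 1, 2] - tri[:, 0, 2]) * (tri[:, 2, 0] - tri[:, 0, 0])
    )
    ybar = tri[:, :, 1].mean(axis=1)
    return float(-(a2 * ybar).sum())


def sample_surface(mesh: trimesh.Trimesh, count: int, rng: np.random.Generator):
    """Deterministic area-weighted surface sampling.

    Returns ``(points, face_index)``.
    """
    area = mesh.area_faces
    probs = area / area.sum()
    face_idx = rng.choice(len(probs), size=count, p=probs)
    r1 = np.sqrt(rng.random(count))
    r2 = rng.random(count)
    tri = mesh.triangles[face_idx]
    pts = (
        (1.0 - r1)[:, None] * tri[:, 0]
        + (r1 * (1.0 - r2))[:, None] * tri[:, 1]
        + (r1 * r2)[:, None] * tri[:, 2]
    )
    return pts, face_idx


def _refine_triangles(tri: np.ndarray, max_reach: float, max_passes: int = 40):
    """Split triangles along their longest edge until every piece fits in a
    ball of radius ``max_reach`` about its centroid; returns
    (refined_triangles, parent_face_index).

    The refined pieces lie exactly on the originals, so closest-point
    results against them are closest points on the original surface.
    """
    parent = np.arange(len(tri))
    for _ in range(max_passes):
        cen = tri.mean(axis=1)
        reach = np.linalg.norm(tri - cen[:, None, :], axis=2).max(axis=1)
        need = reach > max_reach
        if not need.any():
            break
        e = np.stack(
            [
                np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1),
                np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1),
                np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1),
            ],
            axis=1,
        )
        longest = e.argmax(axis=1)
        keep_tri, keep_par = tri[~need], parent[~need]
        t = tri[need]
        li = longest[need]
        # opposite vertex index = li; edge endpoints are the other two
        a = t[np.arange(len(t)), (li + 1) % 3]
        b = t[np.arange(len(t)), (li + 2) % 3]
        c = t[np.arange(len(t)), li]
        mid = 0.5 * (a + b)
        t1 = np.stack([c, a, mid], axis=1)
        t2 = np.stack([c, mid, b], axis=1)
        tri = np.concatenate([keep_tri, t1, t2])
        parent = np.concatenate([keep_par, parent[need], parent[need]])
    return tri, parent


class SurfaceQuery:
    """Closest-point-on-surface queries via a centroid KD-tree.

    The tree is built over a refined copy of the triangles (long edges
    split) so that centroid k-nearest candidates always cover the surface
    area near the query point, even for long skinny triangles; the exact
    point-triangle distance is then minimized over candidates.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 64):
        self.mesh = mesh
        tri = mesh.triangles
        edges = np.linalg.norm(tri[:, [1, 2, 0]] - tri, axis=2)
        max_reach = max(0.75 * float(np.median(edges)), 1e-6)
        self._rtri, self._parent = _refine_triangles(tri, max_reach)
        # farthest point of a refined piece from its centroid
        cen = self._rtri.mean(axis=1)
        self._reach = float(
            np.linalg.norm(self._rtri - cen[:, None, :], axis=2).max()
        )
        self.k = int(min(k, len(self._rtri)))
        self._tree = cKDTree(cen)
        self._normals = mesh.face_normals

    def _exact(self, points, cand):
        n, m = cand.shape
        flat_pts = np.repeat(points, m, axis=0)
        flat_tri = self._rtri[cand.ravel()]
        closest = trimesh.triangles.closest_point(flat_tri, flat_pts)
        d2 = ((closest - flat_pts) ** 2).sum(axis=1).reshape(n, m)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        return (
            closest.reshape(n, m, 3)[rows, best],
            np.sqrt(d2[rows, best]),
            self._parent[cand[rows, best]],
        )

    def query(self, points: np.ndarray):
        """Return ``(closest_points, distances, face_indices)``.

        Exact: any piece that could beat the current best must have its
        centroid within ``best + reach``; if the k-NN shell is narrower than
        that the search escalates k for the affected points.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        k = self.k
        dc, cand = self._tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        dc = np.atleast_2d(dc)
        cp, dist, face_idx = self._exact(points, cand)
        # completeness check: shell must extend past best + reach
        pending = dc[:, -1] < dist + self._reach
        while pending.any() and k < len(self._rtri):
            k = min(4 * k, len(self._rtri))
            idx = np.nonzero(pending)[0]
            dc2, cand2 = self._tree.query(points[idx], k=k)
            cand2 = np.atleast_2d(cand2)
            dc2 = np.atleast_2d(dc2)
            cp2, dist2, fi2 = self._exact(points[idx], cand2)
            cp[idx], dist[idx], face_idx[idx] = cp2, dist2, fi2
            done = dc2[:, -1] >= dist2 + self._reach
            pending[idx[done]] = False
            if k == len(self._rtri):
                break
        return cp, dist, face_idx

    def signed_distance(self, points: np.ndarray):
        """Distance with sign: positive when the point lies outside along the
        closest face's outward normal."""
        cp, dist, fi = self.query(points)
        sign = np.sign(np.einsum("ij,ij->i", points - cp, self._normals[fi]))
        sign[sign == 0.0] = 1.0
        return sign * dist, cp, fi


# ---------------------------------------------------------------------------
# polygon triangulation (ear clipping, holes by bridging)
# ---------------------------------------------------------------------------

def _ring_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _cross2(a, b) -> float:
    return a[0] * b[1] - a[1] * b[0]


def _segments_intersect(p1, p2, q1, q2) -> bool:
    """Proper intersection test for open segments (shared endpoints ignored)."""
    d1 = _cross2(q2 - q1, p1 - q1)
    d2 = _cross2(q2 - q1, p2 - q1)
    d3 = _cross2(p2 - p1, q1 - p1)
    d4 = _cross2(p2 - p1, q2 - p1)
    return bool(((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)))


def _bridge_hole(outer: list, hole: list, pts: np.ndarray) -> list:
    """Splice ``hole`` into ``outer`` through a mutually visible vertex pair.

    ``outer``/``hole`` are lists of indices into ``pts``.  Candidate pairs are
    tried nearest-first; a pair is accepted when the bridge segment crosses no
    edge of either ring.
    """
    o = np.asarray(outer)
    h = np.asarray(hole)
    # nearest-first candidate pairs
    d = ((pts[o][:, None, :] - pts[h][None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d, axis=None)
    edges = []
    for ring in (outer, hole):
        for i in range(len(ring)):
            edges.append((ring[i], ring[(i + 1) % len(ring)]))
    for flat in order[: max(200, len(order) // 4)]:
        oi, hi = np.unravel_index(flat, d.shape)
        a, b = outer[oi], hole[hi]
        pa, pb = pts[a], pts[b]
        ok = True
        for (e1, e2) in edges:
            if a in (e1, e2) or b in (e1, e2):
                continue
            if _segments_intersect(pa, pb, pts[e1], pts[e2]):
                ok = False
                break
        if ok:
            return (
                outer[: oi + 1]
                + hole[hi:]
                + hole[: hi + 1]
                + outer[oi:]
            )
    raise GeometryError("could not bridge hole into outer ring")


def triangulate_ring_indices(pts: np.ndarray, ring: list) -> list:
    """Ear-clip a simple polygon given as vertex indices into ``pts`` (CCW).

    Collinear vertices produce zero-area triangles, which are kept so that
    boundary edges match adjacent wall faces exactly.
    """
    ring = list(ring)
    tris = []
    guard = 0
    scale = max(np.ptp(pts[ring], axis=0).max(), 1.0)
    eps = 1e-12 * scale * scale
    while len(ring) > 3:
        n = len(ring)
        clipped = False
        # prefer strictly convex ears, fall back to degenerate ones
        for pass_eps in (eps, -eps):
            for i in range(n):
                a, b, c = ring[i - 1], ring[i], ring[(i + 1) % n]
                pa, pb, pc = pts[a], pts[b], pts[c]
                cross = (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (pc[0] - pa[0])
                if cross < pass_eps:
                    continue
                # no other ring vertex strictly inside the candidate ear
                ok = True
                if cross > eps:
                    for j in ring:
                        if j in (a, b, c):
                            continue
                        p = pts[j]
                        w0 = (pb[0] - pa[0]) * (p[1] - pa[1]) - (pb[1] - pa[1]) * (p[0] - pa[0])
                        w1 = (pc[0] - pb[0]) * (p[1] - pb[1]) - (pc[1] - pb[1]) * (p[0] - pb[0])
                        w2 = (pa[0] - pc[0]) * (p[1] - pc[1]) - (pa[1] - pc[1]) * (p[0] - pc[0])
                        if w0 > eps and w1 > eps and w2 > eps:
                            ok = False
                            break
                if ok:
                    tris.append((a, b, c))
                    ring.pop(i)
                    clipped = True
                    break
            if clipped:
                break
        if not clipped:
            # numerical dead end: clip the most convex vertex unconditionally
            best_i, best_cross = 0, -np.inf
            for i in range(n):
                a, b, c = ring[i - 1], ring[i], ring[(i + 1) % n]
                pa, pb, pc = pts[a], pts[b], pts[c]
                cross = (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (pc[0] - pa[0])
                if cross > best_cross:
                    best_i, best_cross = i, cross
            a, b, c = ring[best_i - 1], ring[best_i], ring[(best_i + 1) % n]
            tris.append((a, b, c))
            ring.pop(best_i)
        guard += 1
        if guard > 100000:
            raise GeometryError("ear clipping did not terminate")
    if len(ring) == 3:
        tris.append(tuple(ring))
    return tris


def triangulate_polygon_with_holes(pts: np.ndarray, outer: list, holes: list) -> list:
    """Triangulate a polygon (vertex-index rings) possibly containing holes.

    ``outer`` must be CCW, holes CW (in the 2D coordinates of ``pts``).
    Returns triangles as index triplets; bridge edges appear twice in
    opposite directions so the result still closes watertight caps.
    """
    ring = list(outer)
    # bridge holes one at a time, rightmost hole first
    remaining = sorted(holes, key=lambda h: -pts[h][:, 0].max())
    for hole in remaining:
        ring = _bridge_hole(ring, list(hole), pts)
    return triangulate_ring_indices(pts, ring)


# ---------------------------------------------------------------------------
# boundary loops / slicing with caps
# ---------------------------------------------------------------------------

def boundary_loops(faces: np.ndarray, pos2: np.ndarray | None = None) -> list:
    """Ordered vertex-index loops of boundary (once-used) edges.

    Directed boundary edges inherit the face winding, so loops come out
    consistently oriented with the surface.  A vertex the boundary passes
    through twice (a "pinch", e.g. where two cut planes meet on a mesh
    vertex) is resolved into separate simple loops; this needs the planar
    vertex coordinates ``pos2`` for the angular tie-break.
    """
    faces = np.asarray(faces)
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    face_of = np.tile(np.arange(len(faces)), 3)
    keys = np.sort(edges, axis=1)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    mask = counts[inv] == 1
    boundary = edges[mask]
    bfaces = face_of[mask]

    out_map: dict = {}
    for ei, (a, b) in enumerate(boundary):
        out_map.setdefault(int(a), []).append(ei)

    has_pinch = any(len(v) > 1 for v in out_map.values())
    side = 1.0
    if has_pinch:
        if pos2 is None:
            raise GeometryError(
                "boundary pinch found but no planar coordinates supplied"
            )
        # which side of the directed boundary the surface lies on (consistent)
        side = 0.0
        for ei in range(len(boundary)):
            a, b = boundary[ei]
            tri = faces[bfaces[ei]]
            cen = pos2[tri].mean(axis=0)
            d = pos2[b] - pos2[a]
            s = d[0] * (cen[1] - pos2[a][1]) - d[1] * (cen[0] - pos2[a][0])
            if abs(s) > 1e-12:
                side = np.sign(s)
                break
        if side == 0.0:
            side = 1.0

    used = np.zeros(len(boundary), dtype=bool)
    loops = []
    for start_edge in range(len(boundary)):
        if used[start_edge]:
            continue
        loop = []
        ei = start_edge
        guard = 0
        while not used[ei]:
            used[ei] = True
            a, b = int(boundary[ei][0]), int(boundary[ei][1])
            loop.append(a)
            cand = [e for e in out_map.get(b, []) if not used[e]]
            if int(boundary[start_edge][0]) == b:
                # closing the loop must compete with continuing through a pinch
                cand.append(start_edge)
            if not cand:
                break
            if len(cand) == 1:
                ei = cand[0]
            else:
                # pinch: keep the wedge bounded by the incoming edge —
                # first outgoing edge rotating from the reversed incoming
                # direction toward the surface side
                d_in = pos2[b] - pos2[a]
                base = np.arctan2(-d_in[1], -d_in[0])
                best, best_ang = cand[0], np.inf
                for e in cand:
                    bb = int(boundary[e][1])
                    d_out = pos2[bb] - pos2[b]
                    ang = np.arctan2(d_out[1], d_out[0]) - base
                    ang = ang % (2.0 * np.pi)
                    if side < 0:
                        ang = 2.0 * np.pi - ang
                    if 1e-12 < ang < best_ang:
                        best, best_ang = e, ang
                ei = best
            guard += 1
            if guard > len(boundary) + 1:
                raise GeometryError("boundary walk did not terminate")
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def plane_basis(normal: np.ndarray) -> tuple:
    """A deterministic (u, v) in-plane basis with ``v = u x n``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([0.0, 0.0, 1.0])
    u = seed - np.dot(seed, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(u, n)
    return u, v


def slice_and_cap(
    mesh: trimesh.Trimesh,
    plane_origin,
    plane_normal,
) -> tuple:
    """Keep the half of ``mesh`` on the positive side of the plane and cap it.

    Returns ``(capped_mesh, cap_face_mask, cap_loops_2d, (u, v))`` where
    ``cap_loops_2d`` are the cap boundary rings projected on the in-plane
    basis ``(u, v)`` (outer rings CCW, holes CW).
    """
    plane_origin = np.asarray(plane_origin, dtype=float)
    plane_normal = np.asarray(plane_normal, dtype=float)
    plane_normal = plane_normal / np.linalg.norm(plane_normal)
    sliced = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=plane_normal, plane_origin=plane_origin, cap=False
    )
    if len(sliced.faces) == 0:
        raise GeometryError("plane slice removed the entire mesh")
    # slice_mesh_plane leaves duplicate vertices along the cut; merge them so
    # the open boundary forms clean loops
    verts, faces = merge_close_vertices(
        np.asarray(sliced.vertices), np.asarray(sliced.faces)
    )
    if len(faces) == 0:
        raise GeometryError("plane slice left no non-degenerate faces")
    u, v = plane_basis(plane_normal)
    pts2 = np.column_stack(
        [(verts - plane_origin) @ u, (verts - plane_origin) @ v]
    )
    loops = boundary_loops(faces, pts2)
    if not loops:
        # plane did not intersect: nothing to cap
        m = as_mesh(verts, faces)
        return m, np.zeros(len(faces), dtype=bool), [], (u, v)

    # Classify rings by containment depth (even depth = outer, odd = hole);
    # winding is then normalized explicitly, so no assumption about the
    # orientation the slicer hands back is needed.
    ring_polys = [Polygon(pts2[loop]).buffer(0) for loop in loops]
    depth = []
    for i, loop in enumerate(loops):
        probe = shapely.Point(pts2[loop[0]])
        d = sum(
            1
            for j, poly in enumerate(ring_polys)
            if j != i and poly.contains(probe)
        )
        depth.append(d)
    outers = [i for i, d in enumerate(depth) if d % 2 == 0]
    holes = [i for i, d in enumerate(depth) if d % 2 == 1]
    if not outers:
        raise GeometryError("cap boundary has no outer ring")
    hole_assign = {i: [] for i in outers}
    for h in holes:
        probe = shapely.Point(pts2[loops[h][0]])
        candidates = [i for i in outers if ring_polys[i].contains(probe)]
        if not candidates:
            raise GeometryError("cap hole is not contained in any outer ring")
        # innermost containing outer ring
        inner = min(candidates, key=lambda i: ring_polys[i].area)
        hole_assign[inner].append(h)
    cap_faces = []
    for i in outers:
        outer_loop = list(loops[i])
        if _ring_area(pts2[outer_loop]) < 0:
            outer_loop = outer_loop[::-1]
        hole_loops = []
        for h in hole_assign[i]:
            hl = list(loops[h])
            if _ring_area(pts2[hl]) > 0:
                hl = hl[::-1]
            hole_loops.append(hl)
        cap_faces.extend(triangulate_polygon_with_holes(pts2, outer_loop, hole_loops))
    cap_faces = np.asarray(cap_faces, dtype=np.int64)
    # orient the cap outward (along -n)
    p = verts[cap_faces[0]]
    n_face = np.cross(p[1] - p[0], p[2] - p[0])
    if np.dot(n_face, plane_normal) > 0:
        cap_faces = cap_faces[:, ::-1]
    all_faces = np.vstack([faces, cap_faces])
    mask = np.zeros(len(all_faces), dtype=bool)
    mask[len(faces):] = True
    capped = as_mesh(verts, all_faces)
    cap_loops_2d = [pts2[loops[i]] for i in outers] + [pts2[loops[i]] for i in holes]
    return capped, mask, cap_loops_2d, (u, v)


# ---------------------------------------------------------------------------
# planar sections
# ---------------------------------------------------------------------------

def section_loops_3d(mesh: trimesh.Trimesh, plane_origin, plane_normal) -> list:
    """Closed 3D polylines of the mesh/plane intersection.

    Segment endpoints are merged at :data:`MERGE_TOL`; each loop is returned
    as an (n, 3) array without repeating the first point.
    """
    plane_origin = np.asarray(plane_origin, dtype=float)
    plane_normal = np.asarray(plane_normal, dtype=float)
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=plane_normal, plane_origin=plane_origin
    )
    if len(segs) == 0:
        return []
    pts = segs.reshape(-1, 3)
    keys = np.round(pts / MERGE_TOL).astype(np.int64)
    _, idx, inv = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    uniq = pts[idx]
    pairs = inv.reshape(-1, 2)
    # drop zero-length segments and exact duplicates
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    adj = {}
    for a, b in pairs:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    loops = []
    visited = set()
    for start in adj:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        closed = False
        while True:
            nbrs = [x for x in adj[cur] if x != prev]
            if not nbrs:
                break  # open chain (tangential slice); discard
            nxt = nbrs[0]
            if nxt == start:
                closed = True
                break
            if nxt in visited:
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        if closed and len(loop) >= 3:
            loops.append(uniq[loop])
    return loops


def loops_to_polygon(loops2d: list) -> MultiPolygon:
    """Assemble 2D rings (any orientation) into a valid (multi)polygon.

    Rings are combined by even-odd nesting, which handles caps with holes.
    """
    polys = []
    for ring in loops2d:
        p = Polygon(ring)
        if not p.is_valid:
            p = p.buffer(0)
        if not p.is_empty:
            polys.append(p)
    if not polys:
        raise GeometryError("no closed rings to polygonize")
    out = polys[0]
    for p in polys[1:]:
        out = out.symmetric_difference(p)
    if out.geom_type == "Polygon":
        out = MultiPolygon([out])
    return out


# ---------------------------------------------------------------------------
# vertical prism volume integral
# ---------------------------------------------------------------------------

def _clip_halfplane(ring: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Sutherland–Hodgman clip of ``ring`` to ``g <= 0``.

    ``g`` holds the (affine) predicate values at the ring vertices; affine
    interpolation along the edges keeps the clip exact for affine ``g``.
    """
    n = len(ring)
    out = []
    for i in range(n):
        j = (i + 1) % n
        pi, pj = ring[i], ring[j]
        gi, gj = g[i], g[j]
        if gi <= 0.0:
            out.append((pi, gi))
            if gj > 0.0:
                t = gi / (gi - gj)
                out.append((pi + t * (pj - pi), 0.0))
        elif gj <= 0.0:
            t = gi / (gi - gj)
            out.append((pi + t * (pj - pi), 0.0))
    if not out:
        return np.empty((0, 2)), np.empty((0,))
    pts = np.array([p for p, _ in out])
    gv = np.array([x for _, x in out])
    return pts, gv


def _ring_area_centroid(ring: np.ndarray):
    if len(ring) < 3:
        return 0.0, np.zeros(2)
    x, y = ring[:, 0], ring[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return 0.0, ring.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return a, np.array([cx, cy])


def _relu_integral(ring: np.ndarray, coef: np.ndarray, c: float) -> float:
    """Integral of ``max(0, y(x,z) - c)`` over a (signed) 2D ring.

    The integrand vanishes on the clip line, so boundary ties cost nothing.
    """
    yv = coef[0] + ring @ coef[1:]
    clipped, _ = _clip_halfplane(ring, c - yv)
    if len(clipped) < 3:
        return 0.0
    a, cen = _ring_area_centroid(clipped)
    return a * (coef[0] + cen @ coef[1:] - c)


def _clamp_integral(ring: np.ndarray, coef: np.ndarray, y_min: float, y_max: float) -> float:
    """Integral of ``clamp(y(x,z), y_min, y_max)`` over a 2D ring.

    ``coef = (a, bx, bz)`` with ``y = a + bx*x + bz*z``.  Uses the identity
    ``clamp(y, a, b) = a + relu(y - a) - relu(y - b)`` so the ring only ever
    needs single half-plane clips; signed areas keep it orientation-aware.
    """
    area, cen = _ring_area_centroid(ring)
    if area == 0.0:
        return 0.0
    if np.isinf(y_min) and np.isinf(y_max):
        return area * (coef[0] + cen @ coef[1:])
    if np.isinf(y_min):
        return area * (coef[0] + cen @ coef[1:]) - _relu_integral(ring, coef, y_max)
    total = y_min * area + _relu_integral(ring, coef, y_min)
    if not np.isinf(y_max):
        total -= _relu_integral(ring, coef, y_max)
    return total


def _polygon_rings(geom):
    """Yield (ring_coords, sign) for a shapely geometry; holes get -1.

    Non-polygonal parts (points/lines from tangent intersections) are
    dropped.  Ring orientation is normalized: exteriors CCW, holes CW —
    GEOS makes no orientation promise for operation results.
    """
    if geom.is_empty:
        return
    if geom.geom_type == "Polygon":
        geoms = [geom]
    elif geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        geoms = [g for g in geom.geoms if g.geom_type == "Polygon"]
    else:
        return
    for poly in geoms:
        if poly.is_empty or poly.area == 0.0:
            continue
        ext = np.asarray(poly.exterior.coords)[:-1]
        if _ring_area(ext) < 0:
            ext = ext[::-1]
        yield ext, 1.0
        for hole in poly.interiors:
            ring = np.asarray(hole.coords)[:-1]
            if _ring_area(ring) > 0:
                ring = ring[::-1]
            yield ring, -1.0


def volume_in_vertical_prism(
    mesh: trimesh.Trimesh,
    region,
    y_min: float = -np.inf,
    y_max: float = np.inf,
) -> float:
    """Exact volume of ``mesh`` inside ``{(x,z) in region, y_min<=y<=y_max}``.

    ``region`` is a shapely (Multi)Polygon in the (x, z) plane.  Uses the
    divergence theorem with ``F = (0, clamp(y, y_min, y_max), 0)``: vertical
    prism walls carry no flux, so the integral runs over mesh triangles only,
    each clipped in 2D against the region.
    """
    if region.is_empty:
        return 0.0
    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)
    tri = verts[faces]
    t2 = tri[:, :, [0, 2]]  # (x, z)
    ty = tri[:, :, 1]
    a2 = 0.5 * (
        (t2[:, 1, 0] - t2[:, 0, 0]) * (t2[:, 2, 1] - t2[:, 0, 1])
        - (t2[:, 1, 1] - t2[:, 0, 1]) * (t2[:, 2, 0] - t2[:, 0, 0])
    )
    nonvert = np.abs(a2) > VERTICAL_TOL

    minx, miny_r, maxx, maxy_r = region.bounds
    bb_lo = t2.min(axis=1)
    bb_hi = t2.max(axis=1)
    overlap = (
        (bb_hi[:, 0] >= minx)
        & (bb_lo[:, 0] <= maxx)
        & (bb_hi[:, 1] >= miny_r)
        & (bb_lo[:, 1] <= maxy_r)
    )
    active = nonvert & overlap
    if not active.any():
        return 0.0

    # boundary STRtree to find triangles needing exact clipping
    boundary_segs = []
    for ring, _ in _polygon_rings(region):
        closed = np.vstack([ring, ring[:1]])
        for i in range(len(ring)):
            boundary_segs.append(shapely.LineString(closed[i : i + 2]))
    btree = STRtree(boundary_segs)

    # vectorized containment of all triangle vertices
    pts_flat = shapely.points(t2[active].reshape(-1, 2))
    inside_flat = shapely.contains(region, pts_flat).reshape(-1, 3)
    all_inside = inside_flat.all(axis=1)
    act_idx = np.nonzero(active)[0]

    # triangles whose bbox meets no boundary segment and verts inside: fast path
    boxes = shapely.box(
        bb_lo[act_idx, 0], bb_lo[act_idx, 1], bb_hi[act_idx, 0], bb_hi[act_idx, 1]
    )
    hit_counts = np.zeros(len(act_idx), dtype=bool)
    qi, _ = btree.query(boxes)
    hit_counts[np.unique(qi)] = True
    simple = all_inside & ~hit_counts
    complex_idx = act_idx[~simple]
    simple_idx = act_idx[simple]

    total = 0.0
    # fast path: whole triangle inside the region
    if len(simple_idx):
        for fi in simple_idx:
            ys = ty[fi]
            if ys.min() >= y_min and ys.max() <= y_max:
                total += -a2[fi] * ys.mean()
            else:
                coef = _affine_y(t2[fi], ys)
                s = 1.0 if a2[fi] > 0 else -1.0
                ring = t2[fi] if s > 0 else t2[fi][::-1]
                total += -s * _clamp_integral(ring, coef, y_min, y_max)
    # exact path: clip against the region polygon
    for fi in complex_idx:
        tri_poly = Polygon(t2[fi])
        if not tri_poly.is_valid:
            tri_poly = tri_poly.buffer(0)
        inter = region.intersection(tri_poly)
        if inter.is_empty:
            continue
        coef = _affine_y(t2[fi], ty[fi])
        s = 1.0 if a2[fi] > 0 else -1.0
        for ring, hole_sign in _polygon_rings(inter):
            # shapely gives exteriors CCW, holes CW; signed areas handle both
            total += -s * hole_sign * _clamp_integral(
                ring if hole_sign > 0 else ring[::-1], coef, y_min, y_max
            )
    return total


def _affine_y(t2: np.ndarray, ty: np.ndarray) -> np.ndarray:
    """Coefficients (a, bx, bz) of y = a + bx*x + bz*z over a triangle."""
    m = np.column_stack([np.ones(3), t2])
    return np.linalg.solve(m, ty)


def volume_outside_vertical_prism(mesh, region, y_min=-np.inf, y_max=np.inf) -> float:
    return signed_volume(mesh) - volume_in_vertical_prism(mesh, region, y_min, y_max)


# ---------------------------------------------------------------------------
# extruded sub-mesh (portion of a mesh outside a vertical prism)
# ---------------------------------------------------------------------------

def mesh_outside_vertical_prism(
    mesh: trimesh.Trimesh,
    region,
    y_min: float,
    y_max: float,
) -> trimesh.Trimesh:
    """Surface model of the part of ``mesh`` outside the vertical prism.

    Mesh triangles are clipped in their (x, z) projection against the region;
    the prism side walls are closed with pieces of the true wall planes cut to
    the mesh cross-section.  Adjacent pieces share geometry but not vertices
    (T-junctions), so the result renders and exports cleanly but is not
    guaranteed edge-manifold; volumes of this sub-mesh should be taken with
    :func:`volume_yflux`, which is immune to vertical-wall stitching.
    """
    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)
    tri = verts[faces]
    t2 = tri[:, :, [0, 2]]
    ty = tri[:, :, 1]
    a2 = 0.5 * (
        (t2[:, 1, 0] - t2[:, 0, 0]) * (t2[:, 2, 1] - t2[:, 0, 1])
        - (t2[:, 1, 1] - t2[:, 0, 1]) * (t2[:, 2, 0] - t2[:, 0, 0])
    )
    pts_flat = shapely.points(t2.reshape(-1, 2))
    inside_flat = shapely.contains(region, pts_flat).reshape(-1, 3)
    n_inside = inside_flat.sum(axis=1)

    out_v = []
    out_f = []
    n_emitted = [0]

    def emit(triangle3):
        base = n_emitted[0]
        out_v.append(np.asarray(triangle3))
        out_f.append(np.array([base, base + 1, base + 2]))
        n_emitted[0] = base + 3

    keep_whole = np.nonzero(n_inside == 0)[0]
    cross = np.nonzero((n_inside > 0) & (n_inside < 3))[0]
    # vertices inside does not prove the triangle is enclosed near concave
    # boundary, but for measurement-grade export this classification is ample
    for fi in keep_whole:
        emit(tri[fi])
    for fi in cross:
        if abs(a2[fi]) <= VERTICAL_TOL:
            # near-vertical: keep if the centroid projects outside
            c = t2[fi].mean(axis=0)
            if not region.contains(shapely.Point(c)):
                emit(tri[fi])
            continue
        tri_poly = Polygon(t2[fi])
        if not tri_poly.is_valid:
            tri_poly = tri_poly.buffer(0)
        diff = tri_poly.difference(region)
        if diff.is_empty:
            continue
        coef = _affine_y(t2[fi], ty[fi])
        orient_ccw = a2[fi] > 0
        for ring, hole_sign in _polygon_rings(diff):
            if hole_sign < 0:
                continue  # holes in clipped pieces: vanishingly rare, skip
            idx_ring = list(range(len(ring)))
            tris2 = triangulate_ring_indices(ring, idx_ring)
            for (a, b, c) in tris2:
                p2 = ring[[a, b, c]]
                yv = coef[0] + p2 @ coef[1:]
                p3 = np.column_stack([p2[:, 0], yv, p2[:, 1]])
                if not orient_ccw:
                    p3 = p3[::-1]
                emit(p3)

    # wall pieces: mesh cross-section on each boundary segment's plane;
    # an STRtree over the triangle footprints skips the (many) wall segments
    # nowhere near the mesh
    tri_lo = t2.min(axis=1)
    tri_hi = t2.max(axis=1)
    tri_tree = STRtree(shapely.box(tri_lo[:, 0], tri_lo[:, 1], tri_hi[:, 0], tri_hi[:, 1]))
    for ring, hole_sign in _polygon_rings(region):
        closed = np.vstack([ring, ring[:1]])
        for i in range(len(ring)):
            p1, p2 = closed[i], closed[i + 1]
            seg = p2 - p1
            seg_len = np.linalg.norm(seg)
            if seg_len < MERGE_TOL:
                continue
            lo = np.minimum(p1, p2)
            hi = np.maximum(p1, p2)
            if len(tri_tree.query(shapely.box(lo[0], lo[1], hi[0], hi[1]))) == 0:
                continue
            d = seg / seg_len
            # outward normal of the region boundary in (x, z)
            # exterior rings are CCW in shapely's convention but note the
            # (x, z) plane as seen here: outward = rotate direction by -90deg
            nrm2 = np.array([d[1], -d[0]]) * hole_sign
            plane_o = np.array([p1[0], 0.0, p1[1]])
            plane_n = np.array([nrm2[0], 0.0, nrm2[1]])
            loops3 = section_loops_3d(mesh, plane_o, plane_n)
            if not loops3:
                continue
            dir3 = np.array([d[0], 0.0, d[1]])
            for loop in loops3:
                rel = loop - plane_o
                s = rel @ dir3
                yv = loop[:, 1]
                ring2 = np.column_stack([s, yv])
                ar = _ring_area(ring2)
                if ar < 0:
                    ring2 = ring2[::-1]
                # clip to the segment span and prism y-range
                for gfun in (
                    -ring2[:, 0],
                    ring2[:, 0] - seg_len,
                    y_min - ring2[:, 1],
                    ring2[:, 1] - y_max,
                ):
                    ring2, _ = _clip_halfplane(ring2, gfun)
                    if len(ring2) < 3:
                        break
                if len(ring2) < 3:
                    continue
                area, _ = _ring_area_centroid(ring2)
                if abs(area) < 1e-12:
                    continue
                tris2 = triangulate_ring_indices(ring2, list(range(len(ring2))))
                for (a, b, c) in tris2:
                    q = ring2[[a, b, c]]
                    p3 = (
                        plane_o
                        + q[:, 0:1] * dir3
                        + np.column_stack([np.zeros(3), q[:, 1], np.zeros(3)])
                    )
                    # body outward normal points into the prism (-outward)
                    # section rings are CCW in (s, y); the wall normal of
                    # that winding is dir3 x ey ... orient by test below
                    p3 = p3[::-1]
                    emit(p3)

    if not out_v:
        return as_mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    vv = np.vstack(out_v)
    ff = np.vstack([f.reshape(1, 3) for f in out_f]) if out_f else np.zeros((0, 3), int)
    soup = trimesh.Trimesh(vertices=vv, faces=ff, process=True, validate=False)
    # fix wall winding globally if it flipped the flux volume negative
    if volume_yflux(soup.vertices, soup.faces) < 0:
        soup.invert()
    return soup


# ---------------------------------------------------------------------------
# column (ray-parity) voxelizer
# ---------------------------------------------------------------------------

def _column_hits(verts, faces, x0, z0, dx, dz, nx, nz):
    """All (column_id, y, winding_sign) crossings of vertical grid columns.

    Column (i, k) sits at ``(x0 + i*dx, z0 + k*dz)``.  Fully vectorized over
    candidate (triangle, column) pairs.
    """
    tri = verts[faces]
    t2 = tri[:, :, [0, 2]]
    ty = tri[:, :, 1]
    a2 = 0.5 * (
        (t2[:, 1, 0] - t2[:, 0, 0]) * (t2[:, 2, 1] - t2[:, 0, 1])
        - (t2[:, 1, 1] - t2[:, 0, 1]) * (t2[:, 2, 0] - t2[:, 0, 0])
    )
    keep = np.abs(a2) > VERTICAL_TOL
    t2, ty, a2 = t2[keep], ty[keep], a2[keep]
    if len(t2) == 0:
        return np.empty(0, np.int64), np.empty(0), np.empty(0)
    lo = t2.min(axis=1)
    hi = t2.max(axis=1)
    i0 = np.clip(np.ceil((lo[:, 0] - x0) / dx).astype(np.int64), 0, nx - 1)
    i1 = np.clip(np.floor((hi[:, 0] - x0) / dx).astype(np.int64), -1, nx - 1)
    k0 = np.clip(np.ceil((lo[:, 1] - z0) / dz).astype(np.int64), 0, nz - 1)
    k1 = np.clip(np.floor((hi[:, 1] - z0) / dz).astype(np.int64), -1, nz - 1)
    wx = np.maximum(i1 - i0 + 1, 0)
    wz = np.maximum(k1 - k0 + 1, 0)
    cnt = wx * wz
    sel = cnt > 0
    if not sel.any():
        return np.empty(0, np.int64), np.empty(0), np.empty(0)
    t2, ty, a2 = t2[sel], ty[sel], a2[sel]
    i0, k0, wx, wz, cnt = i0[sel], k0[sel], wx[sel], wz[sel], cnt[sel]
    total = int(cnt.sum())
    tri_id = np.repeat(np.arange(len(cnt)), cnt)
    offs = np.concatenate([[0], np.cumsum(cnt)[:-1]])
    local = np.arange(total) - np.repeat(offs, cnt)
    wz_r = wz[tri_id]
    ix = i0[tri_id] + local // wz_r
    kz = k0[tri_id] + local % wz_r
    px = x0 + ix * dx
    pz = z0 + kz * dz
    # barycentric coordinates in the (x, z) projection
    A = t2[tri_id]
    d = np.column_stack([px, pz])
    v0 = A[:, 1] - A[:, 0]
    v1 = A[:, 2] - A[:, 0]
    v2 = d - A[:, 0]
    den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    w1 = (v2[:, 0] * v1[:, 1] - v2[:, 1] * v1[:, 0]) / den
    w2 = (v0[:, 0] * v2[:, 1] - v0[:, 1] * v2[:, 0]) / den
    w0 = 1.0 - w1 - w2
    inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
    tri_id = tri_id[inside]
    if len(tri_id) == 0:
        return np.empty(0, np.int64), np.empty(0), np.empty(0)
    T = ty[tri_id]
    y = (
        w0[inside] * T[:, 0] + w1[inside] * T[:, 1] + w2[inside] * T[:, 2]
    )
    # winding sign: +1 where the surface faces up (n_y > 0)
    sign = np.where(a2[tri_id] < 0, 1.0, -1.0)
    col = ix[inside] * nz + kz[inside]
    return col, y, sign


def column_intervals(mesh: trimesh.Trimesh, dx: float, dz: float, origin_xz=None, shape=None):
    """Inside-intervals of vertical grid columns through ``mesh``.

    Returns ``(col_ids, y_lo, y_hi, (x0, z0), (nx, nz))``; a column may
    contribute several intervals.  Grid columns are offset from the mesh
    bounds by an irrational-ish fraction of the spacing so that columns
    essentially never hit mesh edges exactly.
    """
    bb = mesh.bounds
    if origin_xz is None:
        x0 = bb[0, 0] + 0.318309886 * dx
        z0 = bb[0, 2] + 0.318309886 * dz
        nx = int(np.floor((bb[1, 0] - x0) / dx)) + 1
        nz = int(np.floor((bb[1, 2] - z0) / dz)) + 1
    else:
        x0, z0 = origin_xz
        nx, nz = shape
    col, y, sign = _column_hits(
        np.asarray(mesh.vertices), np.asarray(mesh.faces), x0, z0, dx, dz, nx, nz
    )
    if len(col) == 0:
        return (np.empty(0, np.int64), np.empty(0), np.empty(0), (x0, z0), (nx, nz))
    order = np.lexsort((-y, col))
    col, y, sign = col[order], y[order], sign[order]
    # winding number accumulated from +infinity downwards, reset per column
    csum = np.cumsum(sign)
    uniq_cols, starts = np.unique(col, return_index=True)
    prior = np.zeros(len(uniq_cols))
    prior[1:] = csum[starts[1:] - 1]
    runs = np.diff(np.append(starts, len(col)))
    col_rank = np.repeat(np.arange(len(uniq_cols)), runs)
    winding = csum - prior[col_rank]
    inside = winding >= 0.5
    # an interval spans from a crossing where winding becomes >=1 down to the
    # next crossing in the same column
    same_col = np.empty(len(col), dtype=bool)
    same_col[:-1] = col[:-1] == col[1:]
    same_col[-1] = False
    start_mask = inside & same_col
    y_hi = y[start_mask]
    y_lo = y[1:][start_mask[:-1]]
    cids = col[start_mask]
    # merge adjacent intervals with coincident endpoints (duplicate hits)
    return cids, y_lo, y_hi, (x0, z0), (nx, nz)


def voxel_inside_points(mesh: trimesh.Trimesh, voxel: float) -> np.ndarray:
    """Centers of a ``voxel``-pitch grid that fall inside ``mesh``."""
    cids, y_lo, y_hi, (x0, z0), (nx, nz) = column_intervals(mesh, voxel, voxel)
    if len(cids) == 0:
        return np.zeros((0, 3))
    bb = mesh.bounds
    yc0 = bb[0, 1] + 0.318309886 * voxel
    j0 = np.ceil((y_lo - yc0) / voxel).astype(np.int64)
    j1 = np.floor((y_hi - yc0) / voxel).astype(np.int64)
    m = np.maximum(j1 - j0 + 1, 0)
    sel = m > 0
    j0, m, cids2 = j0[sel], m[sel], cids[sel]
    total = int(m.sum())
    rep = np.repeat(np.arange(len(m)), m)
    offs = np.concatenate([[0], np.cumsum(m)[:-1]])
    local = np.arange(total) - np.repeat(offs, m)
    jy = j0[rep] + local
    ix = cids2[rep] // nz
    kz = cids2[rep] % nz
    return np.column_stack([x0 + ix * voxel, yc0 + jy * voxel, z0 + kz * voxel])


def occupancy_grid(mesh: trimesh.Trimesh, spacing, pad: int = 3):
    """Boolean inside/outside grid at (possibly anisotropic) ``spacing``.

    Returns ``(grid[ix, iy, iz], origin)`` where ``origin`` is the center of
    voxel (0, 0, 0).  The grid is padded with empty space so an isosurface of
    the volume is always closed.
    """
    spacing = np.asarray(spacing, dtype=float)
    bb = mesh.bounds
    origin = bb[0] - pad * spacing + 0.318309886 * spacing
    n = np.ceil((bb[1] - origin) / spacing).astype(int) + pad + 1
    if int(np.prod(n)) > 1_000_000_000:
        raise GeometryError("voxel grid exceeds 1e9 cells")
    cids, y_lo, y_hi, _, (nx, nz) = column_intervals(
        mesh,
        spacing[0],
        spacing[2],
        origin_xz=(origin[0], origin[2]),
        shape=(int(n[0]), int(n[2])),
    )
    grid = np.zeros((int(n[0]), int(n[1]), int(n[2])), dtype=bool)
    if len(cids) == 0:
        return grid, origin
    j0 = np.ceil((y_lo - origin[1]) / spacing[1]).astype(np.int64)
    j1 = np.floor((y_hi - origin[1]) / spacing[1]).astype(np.int64)
    j0 = np.clip(j0, 0, int(n[1]) - 1)
    j1 = np.clip(j1, -1, int(n[1]) - 1)
    ix = cids // int(n[2])
    kz = cids % int(n[2])
    for a, b, i, k in zip(j0, j1, ix, kz):
        if b >= a:
            grid[i, a : b + 1, k] = True
    return grid, origin
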
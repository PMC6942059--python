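"""Anatomical tibial coordinate system from the tangent-rectangle construction.

The frame is built the way it is measured clinically on an osteoarthritic
knee: a planar cross-section of the tibia is taken at the top of the fibular
notch — a level low enough to avoid marginal osteophytes — and a rectangle is
fitted tangent to the condylar contours:

* one side on the common posterior tangent of the two condyles,
* medial and lateral sides tangent to the respective condyles,
* the anterior side tangent to the *medial* condyle only.

The rectangle's center, translated superiorly to the bottom of the medial
tibial plateau, is the frame origin; the rectangle sides give the
mediolateral Z and anteroposterior X axes and Y = Z x X points superior.
The frame can be transferred to a second model of the same bone (e.g. the
MRI-derived model when it was fitted on CT) with iterative-closest-point
rigid registration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

from ._geometry import (
    GeometryError,
    SurfaceQuery,
    sample_surface,
    section_loops_3d,
)


class EmptySectionError(GeometryError):
    """The cutting plane does not intersect the mesh."""


class RectangleFitError(GeometryError):
    """The tangent rectangle could not be fitted."""


class FrameError(GeometryError):
    """The coordinate frame could not be constructed."""


class RegistrationError(GeometryError):
    """ICP failed to align the two models."""


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation det +1, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        out = mesh.copy()
        out.vertices = self.apply(out.vertices)
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix().tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(json.loads(text)["matrix"])


# ---------------------------------------------------------------------------
# planar sections and the tangent rectangle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlanarSection:
    """Mesh/plane cross-section as closed 2D contours in the plane basis.

    ``basis_v = basis_u x plane_normal``; contours are CCW by signed area in
    (u, v) and do not repeat their first point.
    """

    plane_point: np.ndarray
    plane_normal: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray
    contours: list

    def to_3d(self, pts2: np.ndarray) -> np.ndarray:
        return (
            self.plane_point
            + np.outer(pts2[:, 0], self.basis_u)
            + np.outer(pts2[:, 1], self.basis_v)
        )


@dataclasses.dataclass
class FittedRectangle:
    """Tangent rectangle in the section plane.

    ``edge_dir_z`` / ``edge_dir_x`` are the mediolateral / anteroposterior
    side directions (3D unit vectors in the plane); tangency points are the
    supporting contour points for each side.
    """

    center: np.ndarray
    edge_dir_z: np.ndarray
    edge_dir_x: np.ndarray
    half_extent_z: float
    half_extent_x: float
    tangency_points: dict
    plane_normal: np.ndarray


@dataclasses.dataclass
class TibialFrame:
    """Anatomical frame: X anteroposterior (anterior +), Y superoinferior
    (superior +), Z mediolateral (medial +), origin at the transferred
    rectangle center."""

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray
    side: str = "right"
    provenance: dict = dataclasses.field(default_factory=dict)

    def rotation(self) -> np.ndarray:
        """World-from-frame rotation; columns are the axes."""
        return np.column_stack([self.axis_x, self.axis_y, self.axis_z])

    def world_to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation()

    def frame_to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation().T + self.origin

    def mesh_to_frame(self, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        out = mesh.copy()
        out.vertices = self.world_to_frame(out.vertices)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "origin": self.origin.tolist(),
                "axis_x": self.axis_x.tolist(),
                "axis_y": self.axis_y.tolist(),
                "axis_z": self.axis_z.tolist(),
                "side": self.side,
                "provenance": _jsonable(self.provenance),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TibialFrame":
        d = json.loads(text)
        return cls(
            origin=np.asarray(d["origin"]),
            axis_x=np.asarray(d["axis_x"]),
            axis_y=np.asarray(d["axis_y"]),
            axis_z=np.asarray(d["axis_z"]),
            side=d.get("side", "right"),
            provenance=d.get("provenance", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def extract_section(
    mesh: trimesh.Trimesh,
    plane_point,
    plane_normal,
    basis_u=None,
) -> PlanarSection:
    """Cross-section of the mesh with a plane, as CCW 2D contours.

    ``basis_u`` defaults to the projection of world +X onto the plane (the
    anteroposterior direction for a superior-facing plane); ``basis_v``
    completes the pair as ``basis_u x normal`` so that for a plane with
    normal +Y, (u, v) = (world X, world Z).
    """
    plane_point = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    if basis_u is None:
        seed = np.array([1.0, 0.0, 0.0])
        if abs(seed @ n) > 0.99:
            seed = np.array([0.0, 0.0, 1.0])
        basis_u = seed - (seed @ n) * n
    basis_u = np.asarray(basis_u, dtype=float)
    basis_u = basis_u / np.linalg.norm(basis_u)
    basis_v = np.cross(basis_u, n)
    loops = section_loops_3d(mesh, plane_point, n)
    if not loops:
        raise EmptySectionError("plane does not intersect the mesh")
    contours = []
    for loop in loops:
        rel = loop - plane_point
        c2 = np.column_stack([rel @ basis_u, rel @ basis_v])
        x, y = c2[:, 0], c2[:, 1]
        area = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area < 0:
            c2 = c2[::-1]
        contours.append(c2)
    return PlanarSection(
        plane_point=plane_point,
        plane_normal=n,
        basis_u=basis_u,
        basis_v=basis_v,
        contours=contours,
    )


def fit_tangent_rectangle(section: PlanarSection, medial_hint) -> FittedRectangle:
    """Fit the four-tangent rectangle to a notch-level section.

    Orientation comes from the posterior common tangent of the two condylar
    arcs (the convex-hull edge whose endpoints straddle the mediolateral
    midline while facing posterior).  ``medial_hint`` is a 2D direction in
    the (u, v) basis that disambiguates medial from lateral; anterior is
    assumed to be roughly +u.
    """
    pts = np.vstack(section.contours)
    if len(pts) < 3:
        raise RectangleFitError("section has fewer than 3 points")
    mhat = np.asarray(medial_hint, dtype=float)
    nrm = np.linalg.norm(mhat)
    if nrm == 0:
        raise RectangleFitError("medial_hint must be non-zero")
    mhat = mhat / nrm
    anterior = np.array([1.0, 0.0])

    hull = ConvexHull(pts)
    hv = pts[hull.vertices]  # CCW
    m_coord = pts @ mhat
    m_mid = 0.5 * (m_coord.min() + m_coord.max())

    zdir2 = None
    best_len = -1.0
    nh = len(hv)
    for i in range(nh):
        a, b = hv[i], hv[(i + 1) % nh]
        d = b - a
        ln = np.linalg.norm(d)
        if ln < 1e-12:
            continue
        d = d / ln
        outward = np.array([d[1], -d[0]])  # CCW hull: outward normal
        if outward @ anterior > -0.3:
            continue  # not posterior-facing
        ma, mb = a @ mhat, b @ mhat
        if (ma - m_mid) * (mb - m_mid) >= 0:
            continue  # both endpoints on the same condyle
        if ln > best_len:
            best_len = ln
            zdir2 = d if d @ mhat > 0 else -d
    if zdir2 is None:
        # merged/ambiguous posterior contour: orientation from the hint,
        # posterior support restricted to the posterior third
        warnings.warn(
            "no posterior bitangent found; falling back to hint orientation",
            stacklevel=2,
        )
        zdir2 = mhat.copy()
    xdir2 = np.array([zdir2[1], -zdir2[0]])
    if xdir2 @ anterior < 0:
        xdir2 = -xdir2

    xs = pts @ xdir2
    zs = pts @ zdir2
    z_mid = 0.5 * (zs.min() + zs.max())
    medial_mask = zs >= z_mid
    if not medial_mask.any():
        raise RectangleFitError("no medial-half points in section")
    post = xs.min()
    ant = xs[medial_mask].max()
    med = zs.max()
    lat = zs.min()
    center2 = 0.5 * (post + ant) * xdir2 + 0.5 * (med + lat) * zdir2

    def to3d(idx: int) -> np.ndarray:
        return section.to_3d(pts[idx][None, :])[0]

    tangency = {
        "posterior": to3d(int(np.argmin(xs))),
        "anterior_medial": to3d(int(np.where(medial_mask)[0][np.argmax(xs[medial_mask])])),
        "medial": to3d(int(np.argmax(zs))),
        "lateral": to3d(int(np.argmin(zs))),
    }
    center3 = section.to_3d(center2[None, :])[0]
    ed_z = zdir2[0] * section.basis_u + zdir2[1] * section.basis_v
    ed_x = xdir2[0] * section.basis_u + xdir2[1] * section.basis_v
    return FittedRectangle(
        center=center3,
        edge_dir_z=ed_z,
        edge_dir_x=ed_x,
        half_extent_z=0.5 * (med - lat),
        half_extent_x=0.5 * (ant - post),
        tangency_points=tangency,
        plane_normal=section.plane_normal,
    )


def build_frame(
    rect: FittedRectangle,
    mesh: trimesh.Trimesh,
    superior_offset: float | None = None,
    side: str = "right",
) -> TibialFrame:
    """Translate the rectangle center superiorly to the bottom of the medial
    plateau and assemble the frame axes.

    When ``superior_offset`` is None it is found automatically as the normal
    distance from the notch plane to the lowest upward-facing articular point
    of the medial plateau region (medial band of the rectangle footprint,
    central 60% in X).  An explicit offset overrides the heuristic.
    """
    axis_z = rect.edge_dir_z / np.linalg.norm(rect.edge_dir_z)
    axis_x = rect.edge_dir_x - (rect.edge_dir_x @ axis_z) * axis_z
    axis_x = axis_x / np.linalg.norm(axis_x)
    axis_y = np.cross(axis_z, axis_x)
    if axis_y @ rect.plane_normal < 0:
        raise FrameError("rectangle axes are inconsistent with the section normal")

    if superior_offset is None:
        verts = np.asarray(mesh.vertices)
        normals = np.asarray(mesh.vertex_normals)
        rel = verts - rect.center
        xr = rel @ axis_x
        zr = rel @ axis_z
        yr = rel @ axis_y
        up = normals @ axis_y > np.cos(np.deg2rad(30.0))
        in_x = np.abs(xr) <= 0.6 * rect.half_extent_x
        in_z = (zr >= 0.1 * rect.half_extent_z) & (zr <= 0.85 * rect.half_extent_z)
        sel = up & in_x & in_z & (yr > 0)
        if not sel.any():
            raise FrameError("no upward-facing medial articular points above the notch plane")
        superior_offset = float(yr[sel].min())

    origin = rect.center + superior_offset * axis_y
    lo, hi = mesh.bounds
    if np.any(origin < lo - 1.0) or np.any(origin > hi + 1.0):
        raise FrameError("frame origin falls outside the mesh bounding box")
    return TibialFrame(
        origin=origin,
        axis_x=axis_x,
        axis_y=axis_y,
        axis_z=axis_z,
        side=side,
        provenance={
            "superior_offset": superior_offset,
            "rect_center": rect.center,
            "half_extent_x": rect.half_extent_x,
            "half_extent_z": rect.half_extent_z,
            "tangency_points": rect.tangency_points,
        },
    )


def fit_tibial_frame(
    mesh: trimesh.Trimesh,
    notch_plane_point,
    notch_plane_normal=(0.0, 1.0, 0.0),
    medial_hint_world=(0.0, 0.0, 1.0),
    superior_offset: float | None = None,
    side: str = "right",
) -> TibialFrame:
    """Convenience pipeline: section at the fibular-notch level, fit the
    tangent rectangle, transfer superiorly, return the frame.

    The fibular-notch level is a user-supplied landmark, as in the manual
    workflow this mirrors.  Left knees are expected pre-mirrored (x -> -x) so
    that medial is always +Z.
    """
    section = extract_section(mesh, notch_plane_point, notch_plane_normal)
    mh3 = np.asarray(medial_hint_world, dtype=float)
    hint2 = np.array([mh3 @ section.basis_u, mh3 @ section.basis_v])
    rect = fit_tangent_rectangle(section, hint2)
    return build_frame(rect, mesh, superior_offset=superior_offset, side=side)


# ---------------------------------------------------------------------------
# ICP registration
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion taking P onto Q."""
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def _point_to_plane_step(moved, closest, normals) -> RigidTransform:
    """Linearized point-to-plane increment for the current correspondences."""
    cxn = np.cross(moved, normals)
    A = np.hstack([cxn, normals])
    b = -np.einsum("ij,ij->i", moved - closest, normals)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    omega, t = x[:3], x[3:]
    angle = np.linalg.norm(omega)
    if angle < 1e-15:
        R = np.eye(3)
    else:
        k = omega / angle
        K = np.array(
            [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, t)


def icp_register(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    n_samples: int = 10000,
    seed: int = 0,
    full_output: bool = False,
):
    """Iterative closest point: rigidly align ``source`` onto ``target``.

    Correspondences are closest points *on the target surface* (not just its
    vertices) for an area-weighted uniform sample of the source surface; each
    step re-solves the absolute transform, which makes the closest-point RMS
    provably non-increasing.  Converged when the RMS change per iteration
    drops below ``tol`` (mm).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = np.random.default_rng(seed)
    pts, _ = sample_surface(source, n_samples, rng)
    query = SurfaceQuery(target)
    normals = np.asarray(target.face_normals)
    xform = init if init is not None else RigidTransform.identity()

    moved = xform.apply(pts)
    closest, dist, fi = query.query(moved)
    trace = [float(np.sqrt(np.mean(dist**2)))]
    for _ in range(max_iter):
        # fast candidate: linearized point-to-plane step
        accepted = None
        cand = _point_to_plane_step(moved, closest, normals[fi]).compose(xform)
        m2 = cand.apply(pts)
        c2, d2, f2 = query.query(m2)
        rms2 = float(np.sqrt(np.mean(d2**2)))
        if rms2 <= trace[-1] + 1e-12:
            accepted = (cand, m2, c2, d2, f2, rms2)
        else:
            # guaranteed-monotone fallback: rigid least squares onto the
            # current closest points
            kab = _kabsch(pts, closest)
            m3 = kab.apply(pts)
            c3, d3, f3 = query.query(m3)
            rms3 = float(np.sqrt(np.mean(d3**2)))
            accepted = (kab, m3, c3, d3, f3, rms3)
        xform, moved, closest, dist, fi, rms = accepted
        if rms > trace[-1] + 1e-9:
            raise RegistrationError(
                f"ICP objective increased ({trace[-1]:.6f} -> {rms:.6f} mm)"
            )
        converged = abs(trace[-1] - rms) < tol
        trace.append(rms)
        if converged:
            break

    diag = float(np.linalg.norm(target.bounds[1] - target.bounds[0]))
    if trace[-1] > 0.5 * diag:
        raise RegistrationError(
            f"ICP did not find overlap (final RMS {trace[-1]:.2f} mm)"
        )
    if full_output:
        return xform, {"rms": trace[-1], "trace": trace, "n_iter": len(trace)}
    return xform


def transfer_frame(frame: TibialFrame, xform: RigidTransform) -> TibialFrame:
    """Map a frame through a rigid transform (axes rotate, origin moves)."""
    R = xform.rotation
    return TibialFrame(
        origin=xform.apply(frame.origin[None, :])[0],
        axis_x=R @ frame.axis_x,
        axis_y=R @ frame.axis_y,
        axis_z=R @ frame.axis_z,
        side=frame.side,
        provenance={**frame.provenance, "transferred": True},
    )


def mirror_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Mirror x -> -x with face winding fixed (left-knee normalization)."""
    out = mesh.copy()
    v = np.asarray(out.vertices).copy()
    v[:, 0] = -v[:, 0]
    out.vertices = v
    out.faces = np.asarray(out.faces)[:, ::-1]
    return out
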
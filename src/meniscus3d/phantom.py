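"""Synthetic knee phantom with analytically known meniscal extrusion.

The phantom emulates an osteoarthritic proximal tibia and medial meniscus
at the level of detail the extrusion measurement actually probes:

* two condylar lobes modelled as overlapping circular cylinders in every
  horizontal cross-section, with vertical walls through the measurement zone
  (plateau level down past the -10 mm reference cut), tapering to a single
  shaft below;
* shallow articular dishes on top (the "bottom of the medial plateau" the
  frame origin is transferred to), an optional medial tibial spine ridge and
  an optional marginal osteophyte bump confined to the rim zone above the
  reference cut;
* a C-shaped meniscal wedge swept around the *medial condyle center* with a
  vertical outer wall at radius ``r_medial + e`` — so the true extrusion
  width is exactly the construction offset ``e`` and the true extrusion
  volume has a closed form (an annular sector with a linearly tapering
  height profile).

CT-like and MRI-like models are derived from the clean meshes by voxelizing
at the respective acquisition resolutions, low-pass filtering, adding
boundary noise and re-extracting an isosurface — the same partial-volume and
slice-thickness degradation that separates real CT- and MRI-derived surface
models.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from skimage.measure import marching_cubes

from . import _geometry as geom
from .mesh_io import smooth_mesh
from .tibial_frame import TibialFrame


class PhantomSpecError(ValueError):
    """Phantom parameters describe impossible geometry."""


@dataclasses.dataclass(frozen=True)
class MeniscusSpec:
    """C-shaped wedge swept around the medial condyle (all mm/degrees).

    The outer wall is vertical at radius ``r_medial + extrusion_mm``; the
    wedge cross-section is a trapezoid ``wedge_width`` wide, ``height_outer``
    tall at the rim tapering to ``height_inner`` at the inner edge, its base
    ``base_y`` above the plateau plane.
    """

    arc_span_deg: float = 150.0
    wedge_width: float = 10.0
    height_outer: float = 4.0
    height_inner: float = 0.8
    base_y: float = 0.3
    extrusion_mm: float = 3.0


@dataclasses.dataclass(frozen=True)
class OsteophyteSpec:
    """Marginal bump on the side wall: angular position (degrees from
    medial, in-plane), radial size, and superoinferior extent below the
    plateau rim."""

    angle_deg: float = 0.0
    radial_mm: float = 3.0
    y_top: float = -0.5
    y_bottom: float = -5.5


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters of the tibia + meniscus pair (mm)."""

    condyle_radii: tuple = (23.0, 23.0)  # (medial, lateral)
    condyle_centers_z: tuple = (17.0, -17.0)  # (medial, lateral)
    shaft_radius: float = 14.0
    shaft_length: float = 80.0
    notch_level_y: float = -20.0
    taper_start_y: float = -13.0
    taper_end_y: float = -38.0
    plateau_drop_y: float = 2.0  # medial articular dish depth
    lateral_dish_ratio: float = 0.7
    meniscus: MeniscusSpec = MeniscusSpec()
    osteophyte: OsteophyteSpec | None = None
    spine_ridge_x: float | None = None
    spine_ridge_height: float = 3.0
    side: str = "right"
    seed: int = 0
    n_theta: int = 512
    ring_spacing: float = 1.0
    n_cap_rings: int = 12


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth stored by the generator."""

    frame: TibialFrame
    width: float  # extrusion width measured on the Z axis (closed form)
    width_max: float  # maximum extrusion width over X (= construction e)
    volume: float  # extrusion volume (closed form), mm^3
    notch_contours: int
    topology_flags: str = ""


# ---------------------------------------------------------------------------
# cross-section machinery
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _level_circles(spec: PhantomSpec, y: float):
    """(centers_z, radii) of the two cross-section circles at height y."""
    s = _smoothstep((y - spec.taper_end_y) / (spec.taper_start_y - spec.taper_end_y))
    cz = np.array(spec.condyle_centers_z) * s
    radii = spec.shaft_radius + (np.array(spec.condyle_radii) - spec.shaft_radius) * s
    return cz, radii


def _star_radius(theta: np.ndarray, cz: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Radial distance from the origin to the union-of-circles outline.

    Valid because the origin lies inside both circles (union star-shaped).
    """
    dz = np.sin(theta)
    best = np.zeros_like(theta)
    for c, r in zip(cz, radii):
        if r <= abs(c):
            raise PhantomSpecError("origin falls outside a condyle circle")
        disc = r * r - c * c + (c * dz) ** 2
        t = c * dz + np.sqrt(disc)
        best = np.maximum(best, t)
    return best


def _osteophyte_bump(spec: PhantomSpec, theta: np.ndarray, y: float) -> np.ndarray:
    o = spec.osteophyte
    if o is None or not (o.y_bottom <= y <= o.y_top):
        return np.zeros_like(theta)
    # medial direction is theta = +90 degrees in the (x, z) plane
    th0 = np.deg2rad(90.0 + o.angle_deg)
    dth = np.arctan2(np.sin(theta - th0), np.cos(theta - th0))
    ang = np.cos(np.clip(dth / np.deg2rad(25.0), -1.0, 1.0) * np.pi / 2.0) ** 2
    tmid = (y - o.y_bottom) / (o.y_top - o.y_bottom)
    prof = np.sin(np.pi * np.clip(tmid, 0.0, 1.0)) ** 2
    return o.radial_mm * ang * prof


def _notch_dent(spec: PhantomSpec, theta: np.ndarray, y: float) -> np.ndarray:
    """Small lateral indentation below the fibular-notch level (cosmetic)."""
    top = spec.notch_level_y
    if y >= top - 1e-9:
        return np.zeros_like(theta)
    depth_prof = _smoothstep((top - y) / 3.0) * _smoothstep((y - (top - 9.0)) / 3.0)
    th0 = np.deg2rad(-90.0)  # lateral
    dth = np.arctan2(np.sin(theta - th0), np.cos(theta - th0))
    ang = np.cos(np.clip(dth / np.deg2rad(30.0), -1.0, 1.0) * np.pi / 2.0) ** 2
    return -1.5 * depth_prof * ang


def _outline(spec: PhantomSpec, theta: np.ndarray, y: float) -> np.ndarray:
    cz, radii = _level_circles(spec, y)
    r = _star_radius(theta, cz, radii)
    r = r + _osteophyte_bump(spec, theta, y) + _notch_dent(spec, theta, y)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])  # (x, z)


def _dish_depth(spec: PhantomSpec, xz: np.ndarray) -> np.ndarray:
    """Articular dish depression depth at top-surface points (>= 0)."""
    depth = np.zeros(len(xz))
    cz, radii = _level_circles(spec, 0.0)
    depths = (spec.plateau_drop_y, spec.plateau_drop_y * spec.lateral_dish_ratio)
    for c, r, d in zip(cz, radii, depths):
        rd = 0.8 * r
        dist2 = xz[:, 0] ** 2 + (xz[:, 1] - c) ** 2
        bowl = d * np.maximum(0.0, 1.0 - dist2 / (rd * rd))
        depth = np.maximum(depth, bowl)
    return depth


def _spine_ridge(spec: PhantomSpec, xz: np.ndarray, envelope: float) -> np.ndarray:
    if spec.spine_ridge_x is None:
        return np.zeros(len(xz))
    h = spec.spine_ridge_height
    g = np.exp(
        -((xz[:, 0] - spec.spine_ridge_x) ** 2) / (2 * 3.0**2)
        - (xz[:, 1] ** 2) / (2 * 6.0**2)
    )
    return h * g * envelope


# ---------------------------------------------------------------------------
# mesh assembly
# ---------------------------------------------------------------------------

def _build_tibia(spec: PhantomSpec) -> trimesh.Trimesh:
    n = spec.n_theta
    if n % 4 != 0:
        raise PhantomSpecError("n_theta must be divisible by 4")
    theta = np.arange(n) * (2.0 * np.pi / n)

    # ring levels: rim at 0, then offset-grid spacing avoiding special planes
    ys = [0.0]
    y = -0.37
    while y > -spec.shaft_length + 0.75:
        ys.append(y)
        y -= spec.ring_spacing
    ys.append(-spec.shaft_length)

    verts = []
    rings = []
    for yl in ys:
        xz = _outline(spec, theta, yl)
        base = len(verts) * 0  # placeholder
        start = sum(len(v) for v in verts)
        verts.append(np.column_stack([xz[:, 0], np.full(n, yl), xz[:, 1]]))
        rings.append(np.arange(n) + start)
    faces = []
    for j in range(len(rings) - 1):
        u, l = rings[j], rings[j + 1]
        for i in range(n):
            k = (i + 1) % n
            faces.append((u[i], u[k], l[k]))
            faces.append((u[i], l[k], l[i]))
    # bottom cap: fan
    start = sum(len(v) for v in verts)
    verts.append(np.array([[0.0, -spec.shaft_length, 0.0]]))
    bot = rings[-1]
    for i in range(n):
        k = (i + 1) % n
        faces.append((bot[i], start, bot[k]))

    # top cap: concentric scaled rings with dish/ridge relief
    rim_xz = _outline(spec, theta, 0.0)
    K = spec.n_cap_rings
    cap_rings = [rings[0]]  # scale 1 = rim ring (y = 0 there: dish vanishes)
    for k in range(K - 1, 0, -1):
        s = k / K
        xz = rim_xz * s
        envelope = float(np.clip((1.0 - s) / 0.15, 0.0, 1.0))
        yv = -_dish_depth(spec, xz) + _spine_ridge(spec, xz, envelope)
        start = sum(len(v) for v in verts)
        verts.append(np.column_stack([xz[:, 0], yv, xz[:, 1]]))
        cap_rings.append(np.arange(n) + start)
    start = sum(len(v) for v in verts)
    center_xz = np.zeros((1, 2))
    yc = -_dish_depth(spec, center_xz)[0] + _spine_ridge(spec, center_xz, 1.0)[0]
    verts.append(np.array([[0.0, yc, 0.0]]))
    center_id = start
    for kk in range(len(cap_rings) - 1):
        o, nn = cap_rings[kk], cap_rings[kk + 1]
        for i in range(n):
            k = (i + 1) % n
            faces.append((o[i], nn[i], nn[k]))
            faces.append((o[i], nn[k], o[k]))
    inner = cap_rings[-1]
    for i in range(n):
        k = (i + 1) % n
        faces.append((inner[i], center_id, inner[k]))

    mesh = geom.as_mesh(np.vstack(verts), np.asarray(faces, dtype=np.int64))
    if geom.signed_volume(mesh) < 0:
        mesh.invert()
    return mesh


def _frame_directions(spec: PhantomSpec):
    """Closed-form rectangle axes/center at the notch level, and origin.

    Supports of circles under the fitted-rectangle construction are exact:
    the posterior bitangent normal satisfies
    ``n_z = (R_lat - R_med) / (c_med - c_lat)``.
    """
    cz_n, radii_n = _level_circles(spec, spec.notch_level_y)
    c_m, c_l = cz_n
    r_m, r_l = radii_n
    nz = (r_l - r_m) / (c_m - c_l)
    if abs(nz) >= 1.0:
        raise PhantomSpecError("condyle circles admit no posterior bitangent")
    xd = np.array([np.sqrt(1.0 - nz * nz), -nz])  # anterior direction (x, z)
    zd = np.array([-xd[1], xd[0]])  # medial direction
    centers = [np.array([0.0, c_m]), np.array([0.0, c_l])]
    post = min(xd @ c - r for c, r in zip(centers, radii_n))
    ant = xd @ centers[0] + r_m
    meds = [zd @ c + r for c, r in zip(centers, radii_n)]
    lats = [zd @ c - r for c, r in zip(centers, radii_n)]
    center2 = 0.5 * (post + ant) * xd + 0.5 * (max(meds) + min(lats)) * zd
    return xd, zd, center2


def _true_frame(spec: PhantomSpec) -> TibialFrame:
    xd, zd, center2 = _frame_directions(spec)
    origin = np.array([center2[0], -spec.plateau_drop_y, center2[1]])
    return TibialFrame(
        origin=origin,
        axis_x=np.array([xd[0], 0.0, xd[1]]),
        axis_y=np.array([0.0, 1.0, 0.0]),
        axis_z=np.array([zd[0], 0.0, zd[1]]),
        side=spec.side,
        provenance={"source": "phantom construction"},
    )


def _build_meniscus(spec: PhantomSpec) -> trimesh.Trimesh:
    m = spec.meniscus
    r_med = spec.condyle_radii[0]
    c_med = np.array([0.0, spec.condyle_centers_z[0]])  # (x, z)
    r_out = r_med + m.extrusion_mm
    r_in = r_out - m.wedge_width
    if r_in <= 0:
        raise PhantomSpecError("meniscus wedge wider than its outer radius")
    xd, zd, _ = _frame_directions(spec)
    half = np.deg2rad(m.arc_span_deg) / 2.0
    seg = max(int(np.ceil(m.arc_span_deg / 0.5)), 8)
    phis = np.linspace(-half, half, seg + 1)
    y0 = m.base_y
    prof = np.array(
        [
            (r_in, y0),
            (r_out, y0),
            (r_out, y0 + m.height_outer),
            (r_in, y0 + m.height_inner),
        ]
    )
    verts = []
    for phi in phis:
        d = np.cos(phi) * zd + np.sin(phi) * xd
        for rho, yy in prof:
            p2 = c_med + rho * d
            verts.append((p2[0], yy, p2[1]))
    verts = np.asarray(verts)
    faces = []
    for j in range(seg):
        a = 4 * j
        b = 4 * (j + 1)
        for i in range(4):
            k = (i + 1) % 4
            faces.append((a + i, b + i, b + k))
            faces.append((a + i, b + k, a + k))
    faces.append((0, 1, 2))
    faces.append((0, 2, 3))
    last = 4 * seg
    faces.append((last + 0, last + 2, last + 1))
    faces.append((last + 0, last + 3, last + 2))
    mesh = geom.as_mesh(verts, np.asarray(faces, dtype=np.int64))
    if geom.signed_volume(mesh) < 0:
        mesh.invert()
    return mesh


def _true_extrusion(spec: PhantomSpec):
    """Closed-form extrusion width and volume of the wedge outside the
    medial condyle cylinder."""
    m = spec.meniscus
    r_med = spec.condyle_radii[0]
    r_out = r_med + m.extrusion_mm
    r_in = r_out - m.wedge_width
    xd, zd, center2 = _frame_directions(spec)
    c_med = np.array([0.0, spec.condyle_centers_z[0]])
    dx = xd @ (c_med - center2)
    if abs(dx) >= r_med:
        raise PhantomSpecError("frame Z axis misses the medial condyle")
    psi = np.arcsin(abs(dx) / r_out)
    if psi >= np.deg2rad(m.arc_span_deg) / 2.0:
        raise PhantomSpecError("meniscal arc does not cover the frame Z axis")
    width_axis = float(np.sqrt(r_out**2 - dx**2) - np.sqrt(r_med**2 - dx**2))
    a = max(r_in, r_med)
    if a >= r_out:
        return max(width_axis, 0.0), 0.0
    slope = (m.height_outer - m.height_inner) / (r_out - r_in)
    c0 = m.height_inner - slope * r_in
    integral = c0 * (r_out**2 - a**2) / 2.0 + slope * (r_out**3 - a**3) / 3.0
    volume = np.deg2rad(m.arc_span_deg) * integral
    return max(width_axis, 0.0), float(volume)


def _check_spec(spec: PhantomSpec) -> None:
    m = spec.meniscus
    if m.extrusion_mm < 0:
        raise PhantomSpecError("extrusion offset must be >= 0")
    o = spec.osteophyte
    if o is not None:
        r_med = spec.condyle_radii[0]
        r_in = r_med + m.extrusion_mm - m.wedge_width
        y_overlap = o.y_top > m.base_y and o.y_bottom < m.base_y + m.height_outer
        ang_overlap = abs(o.angle_deg) < m.arc_span_deg / 2.0 + 25.0
        if y_overlap and ang_overlap and r_med + o.radial_mm > r_in:
            raise PhantomSpecError("osteophyte would intersect the meniscus")


def make_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build the tibia + meniscus meshes and their ground truth.

    Returns ``(tibia, meniscus, truth)``; both meshes are watertight.  For
    ``side='left'`` the meshes are mirrored (x -> -x); the stored truth
    refers to the mirrored-back (right-equivalent) geometry, matching the
    pipeline convention of normalizing left knees before fitting.
    """
    _check_spec(spec)
    tibia = _build_tibia(spec)
    meniscus = _build_meniscus(spec)
    if not tibia.is_watertight or not meniscus.is_watertight:
        raise PhantomSpecError("phantom construction produced a non-watertight mesh")
    width, volume = _true_extrusion(spec)
    truth = PhantomTruth(
        frame=_true_frame(spec),
        width=width,
        width_max=float(spec.meniscus.extrusion_mm),
        volume=volume,
        notch_contours=1,
        topology_flags="closed_form_truth",
    )
    if spec.side == "left":
        from .tibial_frame import mirror_mesh

        tibia = mirror_mesh(tibia)
        meniscus = mirror_mesh(meniscus)
    return tibia, meniscus, truth


# ---------------------------------------------------------------------------
# acquisition emulation
# ---------------------------------------------------------------------------

#: voxel pitch (x, y, z) mm per modality; MRI stacks 2 mm coronal slices
#: along the anteroposterior (X) axis with ~0.47 mm in-plane sampling
ACQUISITION_SPACING = {
    "ct": (0.5, 0.5, 0.5),
    "mri": (2.0, 0.47, 0.47),
}
#: boundary jitter (standard deviation, mm) per modality
ACQUISITION_JITTER = {"ct": 0.1, "mri": 0.25}


def emulate_acquisition(
    mesh: trimesh.Trimesh, modality: str, seed: int = 0
) -> trimesh.Trimesh:
    """Degrade a clean surface the way a scan + segmentation pipeline would.

    Voxelize at the modality's resolution, low-pass filter (partial-volume
    effect), perturb the implicit boundary with correlated noise scaled to
    the target jitter, re-extract the 0.5 isosurface and lightly smooth.
    Deterministic in ``seed``.
    """
    if modality not in ACQUISITION_SPACING:
        raise ValueError(f"unknown modality {modality!r}")
    if not mesh.is_watertight:
        raise ValueError("acquisition emulation requires a watertight mesh")
    spacing = np.array(ACQUISITION_SPACING[modality])
    jitter = ACQUISITION_JITTER[modality]
    grid, origin = geom.occupancy_grid(mesh, spacing, pad=4)
    field = gaussian_filter(grid.astype(np.float32), sigma=0.9)
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(
        rng.standard_normal(grid.shape).astype(np.float32), sigma=2.0
    )
    sd = float(noise.std())
    if sd > 0:
        noise /= sd
    # scale noise so the implied boundary displacement has the target sigma
    g = np.array(np.gradient(field, *spacing))
    gmag = np.sqrt((g**2).sum(axis=0))
    near = (field > 0.3) & (field < 0.7)
    gm = float(gmag[near].mean()) if near.any() else 1.0
    # keep the border shell noise-free so the isosurface can never be
    # clipped open against the volume boundary
    shell = np.zeros_like(field)
    shell[2:-2, 2:-2, 2:-2] = 1.0
    field = field + jitter * gm * noise * shell
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=tuple(spacing))
    verts = verts + origin
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=True, validate=False)
    if geom.signed_volume(out) < 0:
        out.invert()
    parts = out.split(only_watertight=True)
    if len(parts) > 1:
        out = max(parts, key=lambda p: abs(geom.signed_volume(p)))
        if geom.signed_volume(out) < 0:
            out.invert()
    elif len(parts) == 1:
        out = parts[0]
        if geom.signed_volume(out) < 0:
            out.invert()
    if not out.is_watertight:
        raise geom.GeometryError("isosurface reconstruction is not watertight")
    return smooth_mesh(out, iterations=2, strength=0.5)


# ---------------------------------------------------------------------------
# brute-force voxel oracle
# ---------------------------------------------------------------------------

def voxel_oracle_volume(mesh: trimesh.Trimesh, predicate=None, voxel: float = 0.1) -> float:
    """Independent volume estimate: count voxel centers inside the mesh that
    satisfy ``predicate`` (a vectorized callable on (n, 3) points).

    Error is O(surface area x voxel); keep ``voxel`` <= 0.2 mm.
    """
    if voxel > 0.2:
        raise ValueError("oracle voxel pitch must be <= 0.2 mm")
    pts = geom.voxel_inside_points(mesh, voxel)
    if len(pts) == 0:
        return 0.0
    if predicate is not None:
        pts = pts[np.asarray(predicate(pts), dtype=bool)]
    return float(len(pts)) * voxel**3
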
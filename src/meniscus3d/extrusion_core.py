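"""Medial-plateau reference geometry and meniscal-extrusion metrics.

The measurement chain, all in anatomical frame coordinates:

1. cut the tibia 10 mm inferior to the plateau (frame ZX plane) and at the
   frame XY plane, keeping the medial plateau block;
2. take the cross-section of that block at the -10 mm level and thicken
   (extrude) it 30 mm superiorly into a prism — the reference region whose
   outline is immune to marginal osteophytes above the cut level;
3. meniscal extrusion volume = meniscus volume outside the prism;
   extrusion width = how far the meniscus pokes past the prism's medial
   edge along the Z axis;
4. a conventional 2D width on a single coronal slice is provided for
   comparison with slice-based measurements.

The prism is a vertical extrusion, so "outside the prism" is resolved by
exact 2D polygon clipping (see :mod:`._geometry`) rather than a general mesh
boolean; a brute-force voxel estimate is kept as a fallback that always
returns a number.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import shapely
import trimesh
from shapely.geometry import LineString, MultiPolygon, Polygon, box as shapely_box

from . import _geometry as geom
from ._geometry import GeometryError
from .tibial_frame import TibialFrame


class WidthError(GeometryError):
    """Width is undefined for the given geometry."""


class SelectionError(GeometryError):
    """No coronal slice satisfies the selection criterion."""


@dataclasses.dataclass(frozen=True)
class MeasurementParams:
    """Tunable measurement constants (mm).

    ``cut_depth`` is the distance below the plateau at which the reference
    cross-section is taken (default 10.0 — below the osteophyte zone);
    ``thicken_height`` is the superior extrusion of that cross-section
    (default 30.0).  ``width_mode`` selects the literal reading of the width
    ("axis_line": measured where the Z axis crosses, i.e. at X = 0) or the
    stricter maximum over anteroposterior positions ("max_over_x").
    """

    cut_depth: float = 10.0
    thicken_height: float = 30.0
    width_mode: str = "axis_line"

    def __post_init__(self):
        if self.cut_depth <= 0 or self.thicken_height <= 0:
            raise ValueError("cut_depth and thicken_height must be > 0")
        if self.width_mode not in ("axis_line", "max_over_x"):
            raise ValueError(f"unknown width_mode {self.width_mode!r}")


@dataclasses.dataclass
class PlateauModel:
    """Medial plateau block in frame coordinates, with its cut caps tagged."""

    mesh: trimesh.Trimesh
    frame: TibialFrame
    params: MeasurementParams
    cap_face_mask: np.ndarray
    base_region: MultiPolygon  # cross-section at Y = -cut_depth, in (X, Z)


@dataclasses.dataclass
class ThickenedSection:
    """Prism from extruding the -cut_depth cross-section superiorly."""

    base_polygons: MultiPolygon
    prism: trimesh.Trimesh
    area: float
    y_base: float
    y_top: float


@dataclasses.dataclass
class MMEResult:
    """Extrusion volume/width with the extruded sub-mesh retained."""

    volume: float
    width: float
    extruded_mesh: trimesh.Trimesh
    params: MeasurementParams
    frame_provenance: str = ""
    used_voxel_fallback: bool = False
    flags: list = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "volume_mm3": self.volume,
                "width_mm": self.width,
                "params": dataclasses.asdict(self.params),
                "frame_provenance": self.frame_provenance,
                "used_voxel_fallback": self.used_voxel_fallback,
                "flags": list(self.flags),
            }
        )


@dataclasses.dataclass
class Width2DResult:
    """Single-slice width; 2D points are (y, z) in the coronal plane."""

    width: float
    slice_x: float
    tibia_edge_point: np.ndarray
    meniscus_edge_point: np.ndarray


# ---------------------------------------------------------------------------
# plateau cutting and the thickened section
# ---------------------------------------------------------------------------

def cut_medial_plateau(
    tibia: trimesh.Trimesh,
    frame: TibialFrame,
    params: MeasurementParams = MeasurementParams(),
) -> PlateauModel:
    """Cut the tibia at frame Y = -cut_depth and frame Z = 0, cap the cuts.

    ``tibia`` is given in world coordinates; the result lives in frame
    coordinates.  Raises :class:`GeometryError` when the frame is so
    misplaced that nothing remains.
    """
    if not tibia.is_watertight:
        raise GeometryError("plateau cutting requires a watertight tibia")
    local = frame.mesh_to_frame(tibia)
    try:
        step1, _, _, _ = geom.slice_and_cap(
            local, [0.0, -params.cut_depth, 0.0], [0.0, 1.0, 0.0]
        )
        step2, _, _, _ = geom.slice_and_cap(step1, [0.0, 0.0, 0.0], [0.0, 0.0, 1.0])
    except GeometryError as exc:
        raise GeometryError(f"plateau cut produced no geometry: {exc}") from exc
    if len(step2.faces) == 0:
        raise GeometryError("plateau cut produced no geometry")
    mask = _cut_face_mask(step2, params)
    base = _base_region(step2, params)
    return PlateauModel(
        mesh=step2, frame=frame, params=params, cap_face_mask=mask, base_region=base
    )


def _cut_face_mask(mesh: trimesh.Trimesh, params: MeasurementParams) -> np.ndarray:
    """Faces lying on the two cut planes (the artificial caps)."""
    centroids = mesh.triangles_center
    normals = mesh.face_normals
    on_y = (np.abs(centroids[:, 1] + params.cut_depth) < 1e-6) & (
        np.abs(normals[:, 1]) > 0.99
    )
    on_z = (np.abs(centroids[:, 2]) < 1e-6) & (np.abs(normals[:, 2]) > 0.99)
    return on_y | on_z


def _base_region(mesh: trimesh.Trimesh, params: MeasurementParams) -> MultiPolygon:
    """The bottom-cap outline as a polygon in (X, Z)."""
    centroids = mesh.triangles_center
    normals = mesh.face_normals
    on_base = (np.abs(centroids[:, 1] + params.cut_depth) < 1e-6) & (
        normals[:, 1] < -0.99
    )
    faces = np.asarray(mesh.faces)[on_base]
    if len(faces) == 0:
        raise GeometryError("plateau has no bottom cap at the cut level")
    verts = np.asarray(mesh.vertices)
    loops = geom.boundary_loops(faces, verts[:, [0, 2]])
    rings = [verts[loop][:, [0, 2]] for loop in loops]
    return geom.loops_to_polygon(rings)


def make_thickened_section(plateau: PlateauModel) -> ThickenedSection:
    """Extrude the -cut_depth cross-section superiorly into the prism."""
    params = plateau.params
    region = plateau.base_region
    if region.is_empty:
        raise GeometryError("empty cross-section at the cut level")
    y0 = -params.cut_depth
    y1 = y0 + params.thicken_height
    prism = extrude_region(region, y0, y1)
    return ThickenedSection(
        base_polygons=region,
        prism=prism,
        area=float(region.area),
        y_base=y0,
        y_top=y1,
    )


def extrude_region(region, y0: float, y1: float) -> trimesh.Trimesh:
    """Watertight straight extrusion of an (X, Z) polygon along +Y."""
    all_v = []
    all_f = []
    offset = 0
    polys = region.geoms if region.geom_type == "MultiPolygon" else [region]
    for poly in polys:
        rings = []
        ext = np.asarray(poly.exterior.coords)[:-1]
        if geom._ring_area(ext) < 0:
            ext = ext[::-1]
        rings.append(ext)
        for hole in poly.interiors:
            h = np.asarray(hole.coords)[:-1]
            if geom._ring_area(h) > 0:
                h = h[::-1]
            rings.append(h)
        pts2 = np.vstack(rings)
        idx_rings = []
        start = 0
        for r in rings:
            idx_rings.append(list(range(start, start + len(r))))
            start += len(r)
        cap = geom.triangulate_polygon_with_holes(pts2, idx_rings[0], idx_rings[1:])
        n = len(pts2)
        bottom = np.column_stack([pts2[:, 0], np.full(n, y0), pts2[:, 1]])
        top = np.column_stack([pts2[:, 0], np.full(n, y1), pts2[:, 1]])
        verts = np.vstack([bottom, top])
        faces = []
        # caps: CCW in (x, z) has 3D normal -Y -> bottom as-is, top reversed
        for (a, b, c) in cap:
            faces.append((a, b, c))
            faces.append((c + n, b + n, a + n))
        for ring_idx in idx_rings:
            m = len(ring_idx)
            for i in range(m):
                p = ring_idx[i]
                q = ring_idx[(i + 1) % m]
                faces.append((q, p, p + n))
                faces.append((q, p + n, q + n))
        all_v.append(verts)
        all_f.append(np.asarray(faces, dtype=np.int64) + offset)
        offset += len(verts)
    mesh = geom.as_mesh(np.vstack(all_v), np.vstack(all_f))
    if geom.signed_volume(mesh) < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# extrusion volume and width
# ---------------------------------------------------------------------------

def compute_mme_volume(
    meniscus: trimesh.Trimesh,
    section: ThickenedSection,
    params: MeasurementParams = MeasurementParams(),
) -> MMEResult:
    """Volume of the meniscus outside the thickened cross-sectional prism.

    ``meniscus`` must be watertight and already in frame coordinates.  The
    primary path is the exact clipped surface integral; if polygon clipping
    fails the volume is re-estimated on a 0.1 mm voxel grid and the result
    flagged.  Width is filled in by :func:`compute_mme_width`.
    """
    if not meniscus.is_watertight:
        raise GeometryError("extrusion volume requires a watertight meniscus")
    flags = []
    lo, hi = meniscus.bounds[:, 1]
    if lo < section.y_base - 1e-9 or hi > section.y_top + 1e-9:
        warnings.warn(
            "meniscus extends beyond the prism's superoinferior span; the "
            "overhang counts as extruded",
            stacklevel=2,
        )
        flags.append("outside_prism_y_span")
    used_fallback = False
    try:
        inside = geom.volume_in_vertical_prism(
            meniscus, section.base_polygons, section.y_base, section.y_top
        )
        volume = max(geom.signed_volume(meniscus) - inside, 0.0)
    except Exception:  # noqa: BLE001 - robust fallback path
        volume = _voxel_outside_volume(meniscus, section, voxel=0.1)
        used_fallback = True
        flags.append("voxel_fallback")
    try:
        extruded = geom.mesh_outside_vertical_prism(
            meniscus, section.base_polygons, section.y_base, section.y_top
        )
    except Exception:  # noqa: BLE001
        extruded = geom.as_mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        flags.append("extruded_mesh_unavailable")
    result = MMEResult(
        volume=float(volume),
        width=0.0,
        extruded_mesh=extruded,
        params=params,
        used_voxel_fallback=used_fallback,
        flags=flags,
    )
    result.width = compute_mme_width(meniscus, section, params, volume=volume)
    return result


def _voxel_outside_volume(
    meniscus: trimesh.Trimesh, section: ThickenedSection, voxel: float
) -> float:
    pts = geom.voxel_inside_points(meniscus, voxel)
    if len(pts) == 0:
        return 0.0
    outside = ~_inside_prism_mask(pts, section)
    return float(outside.sum()) * voxel**3


def _inside_prism_mask(points: np.ndarray, section: ThickenedSection) -> np.ndarray:
    in_y = (points[:, 1] >= section.y_base) & (points[:, 1] <= section.y_top)
    pts2 = shapely.points(points[:, [0, 2]])
    in_xz = shapely.contains(section.base_polygons, pts2)
    return in_y & in_xz


def prism_outside_predicate(section: ThickenedSection):
    """Spatial predicate 'outside the prism' for the voxel oracle."""

    def predicate(points: np.ndarray) -> np.ndarray:
        return ~_inside_prism_mask(points, section)

    return predicate


def _prism_edge_z(section: ThickenedSection, x: float) -> float | None:
    """Outermost (max-Z) point of the prism outline at anteroposterior x."""
    zmin = section.base_polygons.bounds[1] - 10.0
    zmax = section.base_polygons.bounds[3] + 10.0
    line = LineString([(x, zmin), (x, zmax)])
    hit = section.base_polygons.intersection(line)
    if hit.is_empty:
        return None
    return float(shapely.bounds(hit)[3])


def _mesh_max_z_at_x(mesh: trimesh.Trimesh, x: float) -> float | None:
    """Max Z of the mesh cross-section at frame X = x (None if no section)."""
    if len(mesh.faces) == 0:
        return None
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=np.array([1.0, 0.0, 0.0]), plane_origin=np.array([x, 0.0, 0.0])
    )
    if len(segs) == 0:
        return None
    return float(segs[:, :, 2].max())


def compute_mme_width(
    meniscus: trimesh.Trimesh,
    section: ThickenedSection,
    params: MeasurementParams = MeasurementParams(),
    volume: float | None = None,
) -> float:
    """Extrusion width: meniscal outer edge minus prism outer edge along Z.

    ``axis_line`` measures on the Z axis (the X = 0 plane); ``max_over_x``
    scans anteroposterior positions at 0.5 mm steps and returns the largest
    protrusion.  Returns 0 for a meniscus entirely inside the prism.
    """
    if volume is None:
        inside = geom.volume_in_vertical_prism(
            meniscus, section.base_polygons, section.y_base, section.y_top
        )
        volume = max(geom.signed_volume(meniscus) - inside, 0.0)
    if volume <= 1e-9 and params.width_mode == "axis_line":
        return 0.0

    if params.width_mode == "axis_line":
        z_men = _mesh_max_z_at_x(meniscus, 0.0)
        if z_men is None:
            return 0.0
        z_prism = _prism_edge_z(section, 0.0)
        if z_prism is None:
            raise WidthError("prism has no outline on the Z axis")
        return float(max(z_men - z_prism, 0.0))

    # max_over_x
    x0, x1 = meniscus.bounds[0, 0], meniscus.bounds[1, 0]
    best = 0.0
    any_prism = False
    for x in np.arange(x0, x1 + 0.25, 0.5):
        z_men = _mesh_max_z_at_x(meniscus, float(x))
        if z_men is None:
            continue
        z_prism = _prism_edge_z(section, float(x))
        if z_prism is None:
            continue
        any_prism = True
        best = max(best, z_men - z_prism)
    if volume > 1e-9 and not any_prism:
        raise WidthError("extrusion present but prism has no outline in its X range")
    return float(max(best, 0.0))


# ---------------------------------------------------------------------------
# 2D (single coronal slice) width
# ---------------------------------------------------------------------------

def select_coronal_slice(
    tibia: trimesh.Trimesh,
    frame: TibialFrame | None,
    spine_region,
    step: float = 0.5,
) -> float:
    """Frame-X of the coronal plane with the greatest sectioned area inside
    ``spine_region`` (a (y0, y1, z0, z1) box or shapely box in (Y, Z)).

    ``tibia`` must already be in frame coordinates when ``frame`` is None.
    Ties break toward anterior (larger X).
    """
    if frame is not None:
        tibia = frame.mesh_to_frame(tibia)
    if not isinstance(spine_region, (Polygon, MultiPolygon)):
        y0, y1, z0, z1 = spine_region
        spine_region = shapely_box(y0, z0, y1, z1)
    bb = tibia.bounds
    if (
        spine_region.bounds[0] > bb[1, 1]
        or spine_region.bounds[2] < bb[0, 1]
        or spine_region.bounds[1] > bb[1, 2]
        or spine_region.bounds[3] < bb[0, 2]
    ):
        raise SelectionError("spine region does not overlap the mesh")
    best_x, best_area = None, 0.0
    for x in np.arange(bb[0, 0] + step / 2, bb[1, 0], step):
        loops = geom.section_loops_3d(tibia, [float(x), 0.0, 0.0], [1.0, 0.0, 0.0])
        if not loops:
            continue
        rings = [loop[:, [1, 2]] for loop in loops]  # (y, z)
        try:
            poly = geom.loops_to_polygon(rings)
        except GeometryError:
            continue
        area = poly.intersection(spine_region).area
        if best_x is None or area >= best_area:
            best_x, best_area = float(x), float(area)
    if best_x is None or best_area <= 0.0:
        raise SelectionError("no coronal section intersects the spine region")
    return best_x


def coronal_contours(mesh: trimesh.Trimesh, slice_x: float) -> list:
    """Closed (y, z) contours of a frame-coordinates mesh at frame X."""
    loops = geom.section_loops_3d(mesh, [slice_x, 0.0, 0.0], [1.0, 0.0, 0.0])
    return [loop[:, [1, 2]] for loop in loops]


def compute_2d_width(
    tibia_contour: np.ndarray,
    meniscus_contour: np.ndarray,
    reference_point,
) -> Width2DResult:
    """Conventional slice-based width: meniscal edge past the plateau edge.

    Contours are (y, z) polygons on one coronal slice; ``reference_point``
    is the plateau-edge point (osteophyte excluded by the caller, as in the
    manual measurement this mirrors).  The reference line is vertical
    (superoinferior) through that point; width is the mediolateral distance
    from it to the outermost meniscal point, clamped at zero.
    """
    tibia_contour = np.asarray(tibia_contour, dtype=float)
    meniscus_contour = np.asarray(meniscus_contour, dtype=float)
    if len(meniscus_contour) == 0:
        raise WidthError("empty meniscus contour")
    ref = np.asarray(reference_point, dtype=float)
    ring = shapely.LinearRing(tibia_contour)
    if ring.distance(shapely.Point(ref)) > 1.0:
        raise WidthError("reference point is more than 1 mm from the tibial contour")
    i_max = int(np.argmax(meniscus_contour[:, 1]))
    men_edge = meniscus_contour[i_max]
    width = float(max(men_edge[1] - ref[1], 0.0))
    return Width2DResult(
        width=width,
        slice_x=float("nan"),
        tibia_edge_point=ref,
        meniscus_edge_point=men_edge,
    )


# ---------------------------------------------------------------------------
# end-to-end measurement
# ---------------------------------------------------------------------------

def measure_extrusion(
    tibia: trimesh.Trimesh,
    meniscus: trimesh.Trimesh,
    frame: TibialFrame,
    params: MeasurementParams = MeasurementParams(),
):
    """Full chain: plateau cut, thickened section, extrusion volume + width.

    Returns ``(MMEResult, ThickenedSection, PlateauModel)``; inputs are in
    world coordinates, the frame does the bookkeeping.
    """
    plateau = cut_medial_plateau(tibia, frame, params)
    section = make_thickened_section(plateau)
    men_local = frame.mesh_to_frame(meniscus)
    result = compute_mme_volume(men_local, section, params)
    result.frame_provenance = json.dumps(
        {"side": frame.side, "origin": frame.origin.tolist()}
    )
    return result, section, plateau
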
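"""Reading, validating, repairing and writing triangulated surface models.

All geometry is in millimetres.  Meshes are carried as
:class:`trimesh.Trimesh`; the loader merges coincident vertices, drops
zero-area faces and re-indexes, so downstream modules can rely on clean
connectivity.  Input meshes may sit in any scanner frame — the anatomical
frame is always fitted, never assumed.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import trimesh

from ._geometry import MERGE_TOL, as_mesh, signed_volume

SUPPORTED_EXTENSIONS = {".stl", ".ply", ".obj"}

_DEGENERATE_AREA = 1e-10  # mm^2


class MeshIOError(IOError):
    """File could not be read or written."""


class MeshValidationError(ValueError):
    """Mesh content violates a precondition."""


@dataclasses.dataclass(frozen=True)
class MeshQuality:
    """Summary report of mesh integrity; computed, never asserted."""

    watertight: bool
    n_components: int
    signed_volume: float
    n_degenerate: int
    bbox: np.ndarray  # (2, 3) min/max corners, mm


def load_mesh(path: str, expect_units: str = "mm") -> trimesh.Trimesh:
    """Load an STL/PLY/OBJ surface model.

    Coincident vertices (within 1e-6 mm) are merged and zero-area faces
    dropped.  Raises :class:`MeshIOError` for unreadable files and
    :class:`MeshValidationError` for empty geometry.
    """
    if expect_units != "mm":
        raise MeshValidationError(f"unsupported unit {expect_units!r}; meshes must be mm")
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise MeshIOError(f"unsupported mesh format {ext!r} for {path}")
    if not os.path.exists(path):
        raise MeshIOError(f"mesh file not found: {path}")
    try:
        raw = trimesh.load(path, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshIOError(f"could not read mesh file {path}: {exc}") from exc
    if raw is None or len(getattr(raw, "faces", [])) == 0:
        raise MeshValidationError(f"mesh file {path} contains no triangles")
    mesh = clean_mesh(raw)
    mesh.metadata["name"] = os.path.splitext(os.path.basename(path))[0]
    if len(mesh.faces) == 0:
        raise MeshValidationError(f"mesh file {path} is empty after validation")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str) -> None:
    """Write a mesh; format follows the extension (binary STL by default)."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise MeshIOError(f"unsupported mesh format {ext!r} for {path}")
    try:
        mesh.export(path)
    except Exception as exc:  # noqa: BLE001
        raise MeshIOError(f"could not write mesh file {path}: {exc}") from exc


def clean_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Merge duplicate vertices, drop degenerate faces, re-index."""
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    # merge within MERGE_TOL via rounding
    keys = np.round(verts / MERGE_TOL).astype(np.int64)
    _, first, inv = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    verts = verts[first]
    faces = inv[faces]
    # drop collapsed and zero-area faces
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    faces = faces[ok]
    tri = verts[faces]
    area = trimesh.triangles.area(tri)
    faces = faces[area > _DEGENERATE_AREA]
    # drop unreferenced vertices
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return as_mesh(verts[used], remap[faces])


def assess_quality(mesh: trimesh.Trimesh) -> MeshQuality:
    """Report watertightness, components, signed volume, degeneracy, bbox.

    Reports, never raises, and never mutates its input.
    """
    faces = np.asarray(mesh.faces)
    area = trimesh.triangles.area(np.asarray(mesh.vertices)[faces])
    try:
        n_comp = len(mesh.split(only_watertight=False))
    except Exception:  # noqa: BLE001 - splitting can fail on junk topology
        n_comp = 1
    return MeshQuality(
        watertight=bool(mesh.is_watertight),
        n_components=max(int(n_comp), 1),
        signed_volume=signed_volume(mesh),
        n_degenerate=int((area <= _DEGENERATE_AREA).sum()),
        bbox=np.array(mesh.bounds, dtype=float),
    )


def smooth_mesh(
    mesh: trimesh.Trimesh, iterations: int = 10, strength: float = 0.5
) -> trimesh.Trimesh:
    """Volume-preserving (Taubin shrink/inflate) smoothing.

    ``iterations`` counts shrink+inflate pairs; ``strength`` in (0, 1) is the
    shrink step.  The inflate step is chosen with the classic pass-band
    relation ``1/strength - 1/inflate = 0.1`` so repeated application does
    not systematically shrink the model, unlike plain Laplacian smoothing.
    Vertex count is unchanged.
    """
    if not mesh.is_watertight:
        raise MeshValidationError("smoothing requires a watertight mesh")
    if not 0.0 < strength < 1.0:
        raise MeshValidationError("strength must be in (0, 1)")
    if iterations < 0:
        raise MeshValidationError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0:
        return out
    inflate = 1.0 / (1.0 / strength - 0.1)
    trimesh.smoothing.filter_taubin(
        out, lamb=strength, nu=inflate, iterations=2 * int(iterations)
    )
    return out
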
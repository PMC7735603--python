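"""Standard pose for tooth-crown meshes.

A crown mesh enters the pipeline with a digitized cervical outline (the
neckline where crown meets root) and a buccal anchor point giving the
anatomical azimuth.  This module fits the total-least-squares plane of
the outline, rotates the mesh so that plane is the ``z = 0`` horizontal,
centres the outline centroid at the origin, shifts the model down so
that exactly the upper 80% of crown height (highest cusp tip to
cervical plane) lies above ``z = 0``, and clips the mesh at that plane.
All downstream sampling happens in this standard pose.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import ComputationError, InputError

__all__ = [
    "CervicalOutline",
    "Plane",
    "OrientedCrown",
    "load_mesh",
    "load_annotated_mesh",
    "fit_cervical_plane",
    "orient_and_crop",
]

#: fraction of crown height kept above the cut plane
CROWN_FRACTION = 0.8


@dataclass
class CervicalOutline:
    """Ordered closed 3D polyline along the cervix (closure implied)."""

    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InputError("cervical outline must be an (n, 3) point array")
        if len(self.points) < 3:
            raise InputError(
                f"cervical outline needs >=3 points, got {len(self.points)}"
            )


@dataclass
class Plane:
    """Plane ``normal . x = offset`` with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isfinite(n) or n == 0:
            raise ComputationError("degenerate plane normal")
        self.normal = self.normal / n
        self.offset = float(self.offset) / n if n != 1.0 else float(self.offset)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset


@dataclass
class OrientedCrown:
    """A crown in standard pose.

    ``mesh`` is the crown clipped at ``z = 0`` (the analysis surface);
    ``full_mesh`` is the same oriented mesh before clipping and is kept
    because vertex normals and discrete curvature are better estimated
    away from the cut boundary.  ``anatomical_zero`` is the azimuth
    (radians) of the buccal direction; angular sampling starts there.
    """

    mesh: trimesh.Trimesh
    full_mesh: trimesh.Trimesh
    crown_height: float
    anatomical_zero: float
    buccal_anchor: np.ndarray
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))
    # lazily filled per-vertex mean curvature of full_mesh (see maps.py)
    _vertex_curvature: np.ndarray | None = field(default=None, repr=False)


def load_mesh(path, outline=None):
    """Read a PLY/OBJ/STL mesh and resolve its cervical outline.

    Parameters
    ----------
    path : str or Path
        Mesh file.  ASCII and binary variants are both accepted.
    outline : sequence of int, str/Path, or None
        Vertex indices of the cervical outline (in file vertex order), or
        the path of a JSON sidecar ``{"outline_indices": [...], ...}``.
        ``None`` looks for ``<path>.json`` next to the mesh.

    Returns
    -------
    (trimesh.Trimesh, CervicalOutline)
        The mesh has merged duplicate vertices and unit vertex normals;
        the outline is resolved to 3D points before any merging, so
        indices always refer to the vertex order of the file.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"mesh file not found: {path}")
    try:
        raw = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - loader errors vary by format
        raise InputError(f"could not read mesh {path}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.vertices) == 0:
        raise InputError(f"empty or non-triangular mesh: {path}")

    indices = None
    if outline is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise InputError(f"no outline given and no sidecar {sidecar}")
        outline = sidecar
    if isinstance(outline, (str, Path)):
        with open(outline) as fh:
            meta = json.load(fh)
        indices = meta["outline_indices"]
    else:
        indices = list(outline)
    indices = np.asarray(indices, dtype=int)
    if len(indices) < 3:
        raise InputError(f"cervical outline needs >=3 points, got {len(indices)}")
    if indices.min() < 0 or indices.max() >= len(raw.vertices):
        raise InputError("outline index out of range for mesh")
    outline_points = np.asarray(raw.vertices, dtype=float)[indices]

    # STL stores unindexed triangles; merge duplicates for a usable surface
    mesh = raw.copy()
    mesh.merge_vertices()
    if len(mesh.faces) == 0:
        raise InputError(f"mesh has no faces: {path}")
    _ = mesh.vertex_normals  # force computation
    return mesh, CervicalOutline(outline_points)


def load_annotated_mesh(path, sidecar=None):
    """Read mesh + sidecar, returning ``(mesh, outline, buccal_anchor)``."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    mesh, outline = load_mesh(path, meta["outline_indices"])
    anchor = np.asarray(meta["buccal_anchor"], dtype=float)
    return mesh, outline, anchor


def fit_cervical_plane(outline: CervicalOutline, orient_toward=None) -> Plane:
    """Total-least-squares plane of the cervical outline.

    Minimizes the sum of squared orthogonal distances (via SVD of the
    centred points; the plane passes through the point centroid).  The
    normal is oriented toward ``orient_toward`` (typically the mesh
    centroid, i.e. the cusp side) when given.
    """
    pts = outline.points
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    scale = float(np.linalg.norm(centred)) or 1.0
    if s[1] <= 1e-10 * scale:
        raise ComputationError("cervical outline points are collinear")
    normal = vt[2]
    if orient_toward is not None:
        side = float(np.dot(np.asarray(orient_toward, float) - centroid, normal))
        if side < 0:
            normal = -normal
    elif normal[2] < 0 or (normal[2] == 0 and normal[np.argmax(np.abs(normal))] < 0):
        normal = -normal
    return Plane(normal=normal, offset=float(normal @ centroid))


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """3x3 rotation taking ``normal`` to +z (minimal rotation)."""
    n = normal / np.linalg.norm(normal)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    c = float(n @ z)
    if np.linalg.norm(v) < 1e-15:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # flip about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def orient_and_crop(
    mesh: trimesh.Trimesh,
    outline: CervicalOutline,
    buccal_anchor,
) -> OrientedCrown:
    """Place a crown in standard pose and clip it at ``z = 0``.

    The cervical plane becomes horizontal with the outline centroid at
    the origin; the model is then shifted down along z so the cut at
    ``z = 0`` retains exactly the upper 80% of crown height.  The clip
    is an exact plane slice (new vertices are created on ``z = 0``), so
    radial section curves terminate exactly at the cut.
    """
    anchor = np.asarray(buccal_anchor, dtype=float)
    plane = fit_cervical_plane(outline, orient_toward=mesh.vertices.mean(axis=0))
    rot = _rotation_to_z(plane.normal)
    centroid = outline.points.mean(axis=0)

    verts = (np.asarray(mesh.vertices, float) - centroid) @ rot.T
    crown_height = float(verts[:, 2].max())
    scale = float(np.ptp(verts, axis=0).max()) or 1.0
    if crown_height <= 0:
        raise ComputationError("crown lies entirely below the cervical plane")
    if crown_height < 1e-9 * scale:
        raise ComputationError("degenerate zero crown height")

    shift = (1.0 - CROWN_FRACTION) * crown_height
    verts = verts - np.array([0.0, 0.0, shift])

    anchor_t = (anchor - centroid) @ rot.T - np.array([0.0, 0.0, shift])
    if np.hypot(anchor_t[0], anchor_t[1]) < 1e-9 * scale:
        raise InputError("buccal anchor lies on the z-axis after orientation")
    azimuth = float(np.arctan2(anchor_t[1], anchor_t[0]))
    # final rotation about z: buccal direction to azimuth 0, making the
    # standard pose unique (anatomical_zero is 0 by construction)
    ca, sa = np.cos(-azimuth), np.sin(-azimuth)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    verts = verts @ rz.T
    anchor_t = rz @ anchor_t
    rot = rz @ rot
    anatomical_zero = 0.0

    full = trimesh.Trimesh(vertices=verts, faces=mesh.faces.copy(), process=False)
    _ = full.vertex_normals
    cropped = trimesh.intersections.slice_mesh_plane(
        full, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, 0.0]
    )
    if cropped is None or len(cropped.faces) == 0:
        raise ComputationError("nothing remains above the cut plane")

    transform = np.eye(4)
    transform[:3, :3] = rot
    transform[:3, 3] = -rot @ centroid - np.array([0.0, 0.0, shift])
    return OrientedCrown(
        mesh=cropped,
        full_mesh=full,
        crown_height=crown_height,
        anatomical_zero=anatomical_zero,
        buccal_anchor=anchor_t,
        transform=transform,
    )
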
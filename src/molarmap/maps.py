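"""Polar morphometric maps of an oriented crown.

The crown surface is cut by ``L`` equiangular vertical half-planes
radiating from the z-axis.  Along each section curve, ``K`` points are
sampled at equal arc-length intervals from the innermost point (nearest
the z-axis) out to the curve's endpoint on ``z = 0``.  Six variables are
recorded per sample — surface curvature ``c`` (discrete mean curvature),
height ``h`` above the basal plane, radius ``r`` from the centroid, and
the unit vertex normal ``(Nx, Ny, Nz)`` — giving six ``K x L`` maps on
polar coordinates ``(d, theta)`` with ``d`` running centre to crown base
and ``theta`` starting at the buccal direction.

Scale is removed by centroid size ``CS = sqrt(sum(h^2 + r^2))`` (h and r
divided by CS, c multiplied by CS since curvature carries units of
1/length).  Before Fourier analysis each cell is weighted by the square
root of its annular-sector area on the unit disk, so that Euclidean
distances between weighted maps realise area-weighted L2 distances
between the raw maps.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import trimesh

from .errors import ComputationError, InputError
from .geometry import OrientedCrown

__all__ = [
    "PARAMETERS",
    "SampleGrid",
    "MorphoMap",
    "MapSet",
    "radial_sample",
    "compute_parameter_maps",
    "centroid_size_normalize",
    "area_weight_matrix",
    "apply_weights",
    "render_map",
    "vertex_mean_curvature",
]

#: the six map variables, in canonical order
PARAMETERS = ("c", "h", "r", "Nx", "Ny", "Nz")

#: default grid resolution (radial x angular)
DEFAULT_K = 300
DEFAULT_L = 300


@dataclass
class SampleGrid:
    """K x L sample points on the crown surface with containing faces."""

    points: np.ndarray  # (K, L, 3)
    faces: np.ndarray  # (K, L) face index into the crown's full mesh
    grid_K: int
    grid_L: int


@dataclass
class MorphoMap:
    """One K x L polar map of a single variable."""

    values: np.ndarray
    parameter: str
    centroid_size: float | None = None
    weighted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.parameter not in PARAMETERS:
            raise InputError(f"unknown map parameter {self.parameter!r}")


@dataclass
class MapSet:
    """The six maps of one specimen."""

    maps: dict  # parameter -> MorphoMap
    specimen_id: str = ""
    group: str = ""

    def __getitem__(self, parameter: str) -> MorphoMap:
        return self.maps[parameter]

    @property
    def grid_shape(self):
        return next(iter(self.maps.values())).values.shape

    @property
    def centroid_size(self):
        return next(iter(self.maps.values())).centroid_size

    @property
    def weighted(self) -> bool:
        return next(iter(self.maps.values())).weighted


# ---------------------------------------------------------------------------
# radial sampling
# ---------------------------------------------------------------------------


def _clip_segments(segs, faces, normal, offset, tol):
    """Keep the parts of line segments with ``normal . p >= offset``."""
    if len(segs) == 0:
        return segs, faces
    s = segs @ normal - offset  # (n, 2)
    keep_full = (s >= -tol).all(axis=1)
    crossing = (s.max(axis=1) > tol) & (s.min(axis=1) < -tol)
    out_segs = [segs[keep_full]]
    out_faces = [faces[keep_full]]
    if crossing.any():
        cs = segs[crossing]
        cv = s[crossing]
        t = cv[:, 0] / (cv[:, 0] - cv[:, 1])
        cut = cs[:, 0] + t[:, None] * (cs[:, 1] - cs[:, 0])
        inside_first = cv[:, 0] >= 0
        new = np.where(
            inside_first[:, None, None],
            np.stack([cs[:, 0], cut], axis=1),
            np.stack([cut, cs[:, 1]], axis=1),
        )
        out_segs.append(new)
        out_faces.append(faces[crossing])
    return np.concatenate(out_segs), np.concatenate(out_faces)


def _chain_segments(segs, faces, tol):
    """Chain unordered segments into polylines.

    Returns a list of ``(points (m,3), edge_faces (m-1,))``.  Endpoints
    within ``tol`` are identified.  Closed loops are opened at an
    arbitrary point (they are never selected as section curves anyway,
    having no endpoint on z = 0).
    """
    from scipy.spatial import cKDTree

    n = len(segs)
    ends = segs.reshape(-1, 3)
    tree = cKDTree(ends)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(ends))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    labels = np.array([find(i) for i in range(len(ends))])

    # adjacency: node -> list of (other node, segment index)
    adj: dict[int, list] = {}
    for si in range(n):
        a, b = labels[2 * si], labels[2 * si + 1]
        if a == b:  # degenerate segment
            continue
        adj.setdefault(a, []).append((b, si))
        adj.setdefault(b, []).append((a, si))

    coord = {}
    for i, lab in enumerate(labels):
        coord.setdefault(lab, ends[i])

    used = np.zeros(n, dtype=bool)
    curves = []

    def walk(start):
        path = [start]
        seg_ids = []
        node = start
        while True:
            nxt = [(o, si) for o, si in adj.get(node, []) if not used[si]]
            if not nxt:
                break
            o, si = nxt[0]
            used[si] = True
            path.append(o)
            seg_ids.append(si)
            node = o
        return path, seg_ids

    open_nodes = [nd for nd, nb in adj.items() if len(nb) == 1]
    for nd in open_nodes:
        if all(used[si] for _, si in adj[nd]):
            continue
        path, seg_ids = walk(nd)
        if seg_ids:
            pts = np.array([coord[p] for p in path])
            curves.append((pts, faces[np.array(seg_ids)]))
    # leftover cycles
    for nd in adj:
        if any(not used[si] for _, si in adj[nd]):
            path, seg_ids = walk(nd)
            if seg_ids:
                pts = np.array([coord[p] for p in path])
                curves.append((pts, faces[np.array(seg_ids)]))
    return curves


def _sample_curve(pts, edge_faces, grid_K):
    """Sample ``grid_K`` points at equal arc length along a polyline.

    Sample k (1-based) sits at arc position ``k/K`` of the total length,
    so the last sample is the curve's endpoint on z = 0.
    """
    deltas = np.diff(pts, axis=0)
    seglen = np.linalg.norm(deltas, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        raise ComputationError("zero-length section curve")
    targets = total * (np.arange(1, grid_K + 1) / grid_K)
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seglen) - 1)
    t = (targets - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    samples = pts[idx] + t[:, None] * deltas[idx]
    return samples, edge_faces[idx]


def radial_sample(
    crown: OrientedCrown, grid_K: int = DEFAULT_K, grid_L: int = DEFAULT_L
) -> SampleGrid:
    """Sample the crown surface on the polar ``(d, theta)`` grid.

    Sections are taken on the oriented pre-crop surface and clipped at
    ``z = 0``, which is identical to sectioning the cropped crown (the
    crop is an exact plane slice) but keeps face indices on the full
    mesh where normals and curvature are estimated.  When a half-plane
    meets the surface in several curve components (overhangs), the
    component ending on ``z = 0`` with the largest mean radius is kept.
    """
    if grid_K < 2 or grid_L < 2:
        raise InputError("grid_K and grid_L must be >= 2")
    mesh = crown.full_mesh
    scale = float(np.ptp(mesh.vertices, axis=0).max()) or 1.0
    tol = 1e-9 * scale
    ztol = 1e-6 * scale

    thetas = crown.anatomical_zero + 2.0 * np.pi * np.arange(grid_L) / grid_L

    # a full plane cut at angle phi serves both phi and phi + pi
    plane_cache: dict[int, tuple] = {}

    def plane_cut(l_idx):
        key = l_idx % (grid_L // 2) if grid_L % 2 == 0 else l_idx
        if key not in plane_cache:
            phi = thetas[key]
            normal = np.array([-np.sin(phi), np.cos(phi), 0.0])
            segs, fids = trimesh.intersections.mesh_plane(
                mesh, plane_normal=normal, plane_origin=[0.0, 0.0, 0.0],
                return_faces=True,
            )
            plane_cache[key] = (np.asarray(segs), np.asarray(fids))
        return plane_cache[key]

    points = np.empty((grid_K, grid_L, 3))
    face_grid = np.empty((grid_K, grid_L), dtype=int)

    for l_idx, theta in enumerate(thetas):
        segs, fids = plane_cut(l_idx)
        if len(segs) == 0:
            raise ComputationError(
                f"section {l_idx}: surface does not intersect the cutting plane"
            )
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        segs_h, fids_h = _clip_segments(segs, fids, direction, 0.0, tol)
        segs_h, fids_h = _clip_segments(
            segs_h, fids_h, np.array([0.0, 0.0, 1.0]), 0.0, tol
        )
        lengths = np.linalg.norm(segs_h[:, 1] - segs_h[:, 0], axis=1) if len(segs_h) else []
        if len(segs_h):
            keep = lengths > tol
            segs_h, fids_h = segs_h[keep], fids_h[keep]
        if len(segs_h) == 0:
            raise ComputationError(
                f"section {l_idx}: no surface above z=0 in this half-plane "
                "(z-axis outside the crown?)"
            )
        curves = _chain_segments(segs_h, fids_h, tol * 10)
        candidates = []
        for pts, efaces in curves:
            endz = min(abs(pts[0, 2]), abs(pts[-1, 2]))
            if endz <= ztol:
                candidates.append((pts, efaces))
        if not candidates:
            raise ComputationError(
                f"section {l_idx}: no section curve reaches the basal plane"
            )
        mean_r = [np.hypot(p[:, 0], p[:, 1]).mean() for p, _ in candidates]
        pts, efaces = candidates[int(np.argmax(mean_r))]
        # orient: curve must end at its z=0 endpoint
        z0, z1 = abs(pts[0, 2]), abs(pts[-1, 2])
        if z0 <= ztol and z1 <= ztol:
            # both ends basal (arch): end at the larger radius
            if np.hypot(*pts[0, :2]) > np.hypot(*pts[-1, :2]):
                pts, efaces = pts[::-1], efaces[::-1]
        elif z0 <= ztol:
            pts, efaces = pts[::-1], efaces[::-1]
        samples, sfaces = _sample_curve(pts, efaces, grid_K)
        samples[-1, 2] = 0.0  # crop contract: row K lies exactly on z = 0
        points[:, l_idx] = samples
        face_grid[:, l_idx] = sfaces

    return SampleGrid(points=points, faces=face_grid, grid_K=grid_K, grid_L=grid_L)


# ---------------------------------------------------------------------------
# parameter maps
# ---------------------------------------------------------------------------


def vertex_mean_curvature(mesh: trimesh.Trimesh) -> np.ndarray:
    """Discrete mean curvature per vertex (cotangent Laplacian).

    The mean-curvature normal at vertex i is
    ``(1 / 2A_i) * sum_j (cot a_ij + cot b_ij)(x_i - x_j)`` with A_i the
    barycentric vertex area; its magnitude is ``2H``.  The sign is taken
    against the outward vertex normal: convex regions (cusp tips, a
    sphere) are positive.  Estimates at open-boundary vertices are
    unreliable, which is why sampling uses the pre-crop surface.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    n = len(v)

    ii, jj, ww = [], [], []
    for k in range(3):
        a, b, c = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        # cotangent of the angle at vertex a, opposite edge (b, c)
        u1 = v[b] - v[a]
        u2 = v[c] - v[a]
        cross = np.cross(u1, u2)
        area2 = np.linalg.norm(cross, axis=1)
        cot = np.einsum("ij,ij->i", u1, u2) / np.maximum(area2, 1e-300)
        ii.extend([b, c])
        jj.extend([c, b])
        ww.extend([0.5 * cot, 0.5 * cot])
    W = sp.coo_matrix(
        (np.concatenate(ww), (np.concatenate(ii), np.concatenate(jj))), shape=(n, n)
    ).tocsr()
    Lmat = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W

    area = np.zeros(n)
    fa = mesh.area_faces / 3.0
    for k in range(3):
        np.add.at(area, f[:, k], fa)

    # with w_ij = (cot a + cot b)/2, L v / (2A) is exactly H * n_hat
    hvec = Lmat @ v / (2.0 * np.maximum(area, 1e-300)[:, None])
    mag = np.linalg.norm(hvec, axis=1)
    sign = np.sign(np.einsum("ij,ij->i", hvec, np.asarray(mesh.vertex_normals)))
    sign[sign == 0] = 1.0
    return mag * sign


def compute_parameter_maps(grid: SampleGrid, crown: OrientedCrown) -> MapSet:
    """Evaluate the six morphometric variables on a sample grid.

    ``h`` and ``r`` come directly from the sample coordinates; the unit
    normal and curvature are barycentrically interpolated from the
    vertices of the containing triangle (normals re-normalized to unit
    length after interpolation).
    """
    mesh = crown.full_mesh
    K, L = grid.grid_K, grid.grid_L
    pts = grid.points.reshape(-1, 3)
    fids = grid.faces.ravel()

    tris = mesh.triangles[fids]
    bary = trimesh.triangles.points_to_barycentric(tris, pts)
    bary = np.clip(bary, 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)

    vn = np.asarray(mesh.vertex_normals)[mesh.faces[fids]]  # (n, 3, 3)
    normals = np.einsum("nk,nkj->nj", bary, vn)
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms < 1e-12):
        raise ComputationError("degenerate interpolated normal at a sample point")
    normals /= norms[:, None]

    if crown._vertex_curvature is None:
        crown._vertex_curvature = vertex_mean_curvature(mesh)
    vc = crown._vertex_curvature[mesh.faces[fids]]
    curv = np.einsum("nk,nk->n", bary, vc)

    h = grid.points[:, :, 2].copy()
    r = np.hypot(grid.points[:, :, 0], grid.points[:, :, 1])
    maps = {
        "c": MorphoMap(curv.reshape(K, L), "c"),
        "h": MorphoMap(h, "h"),
        "r": MorphoMap(r, "r"),
        "Nx": MorphoMap(normals[:, 0].reshape(K, L), "Nx"),
        "Ny": MorphoMap(normals[:, 1].reshape(K, L), "Ny"),
        "Nz": MorphoMap(normals[:, 2].reshape(K, L), "Nz"),
    }
    return MapSet(maps=maps)


# ---------------------------------------------------------------------------
# normalization and weighting
# ---------------------------------------------------------------------------


def centroid_size_normalize(mapset: MapSet) -> MapSet:
    """Remove scale using centroid size computed from the h and r maps.

    ``CS = sqrt(sum_kl (h_kl^2 + r_kl^2))``; h and r are divided by CS,
    c is multiplied by CS (curvature has units 1/length), the unit
    normals are dimensionless and pass through unchanged.
    """
    if mapset.weighted:
        raise InputError("normalize before applying area weights")
    h = mapset["h"].values
    r = mapset["r"].values
    cs = float(np.sqrt(np.sum(h * h + r * r)))
    if cs <= 0:
        raise ComputationError("zero centroid size")
    out = {}
    for p, m in mapset.maps.items():
        if p in ("h", "r"):
            vals = m.values / cs
        elif p == "c":
            vals = m.values * cs
        else:
            vals = m.values.copy()
        out[p] = replace(m, values=vals, centroid_size=cs)
    return MapSet(maps=out, specimen_id=mapset.specimen_id, group=mapset.group)


def area_weight_matrix(grid_K: int, grid_L: int) -> np.ndarray:
    """Annular-sector areas of the concentrically subdivided unit disk.

    Cell (k, l), k = 1..K (1-based), covers radii [(k-1)/K, k/K] and a
    1/L turn, hence area ``pi ((k/K)^2 - ((k-1)/K)^2) / L``; the weights
    sum to pi, the disk area, and do not depend on l.
    """
    if grid_K < 1 or grid_L < 1:
        raise InputError("grid dimensions must be >= 1")
    k = np.arange(1, grid_K + 1)
    ring = np.pi * ((k / grid_K) ** 2 - ((k - 1) / grid_K) ** 2) / grid_L
    return np.repeat(ring[:, None], grid_L, axis=1)


def apply_weights(mapset: MapSet, weights: np.ndarray | None = None) -> MapSet:
    """Multiply each cell by ``sqrt(a_kl / pi)``.

    With square-root multipliers, the plain squared Euclidean distance
    between two weighted maps equals the area-weighted mean squared
    difference of the raw maps (total weight normalized to 1), so
    Fourier-space distances inherit the area-weighted metric.
    """
    if mapset.weighted:
        raise InputError("area weights already applied")
    K, L = mapset.grid_shape
    if weights is None:
        weights = area_weight_matrix(K, L)
    if weights.shape != (K, L):
        raise InputError("weight matrix shape does not match maps")
    mult = np.sqrt(weights / np.pi)
    out = {
        p: replace(m, values=m.values * mult, weighted=True)
        for p, m in mapset.maps.items()
    }
    return MapSet(maps=out, specimen_id=mapset.specimen_id, group=mapset.group)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_map(obj, cmap: str = "viridis", pad_to_cervix: bool = False):
    """Render a map (or the Nxyz triplet of a MapSet) as an RGB image.

    Scalar maps use a matplotlib colormap scaled to the value range.
    For a MapSet the three normal components map linearly to RGB,
    ``[-1, 1] -> [0, 255]`` per channel, so the decode back to the
    normal is exact to half a grey level.  With ``pad_to_cervix`` each
    angular column is radially rescaled to the relative cervical radius
    (the r map's basal row) and the remainder padded with black,
    mimicking the crown outline.
    """
    if isinstance(obj, MapSet):
        if obj.weighted:
            raise InputError("render unweighted maps")
        stack = np.stack([obj[p].values for p in ("Nx", "Ny", "Nz")], axis=-1)
        img = np.clip((stack + 1.0) / 2.0, 0.0, 1.0)
        rgb = np.rint(img * 255).astype(np.uint8)
        rel = None
        if pad_to_cervix:
            r_base = obj["r"].values[-1]
            rel = r_base / r_base.max() if r_base.max() > 0 else None
    else:
        if obj.weighted:
            raise InputError("render unweighted maps")
        from matplotlib import colormaps

        vals = obj.values
        lo, hi = float(vals.min()), float(vals.max())
        scaled = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo)
        rgb = (colormaps[cmap](scaled)[:, :, :3] * 255).astype(np.uint8)
        rel = None

    if pad_to_cervix and rel is not None:
        K, L = rgb.shape[:2]
        out = np.zeros_like(rgb)
        for l_idx in range(L):
            rows = max(1, int(round(K * rel[l_idx])))
            src = np.linspace(0, K - 1, rows).round().astype(int)
            out[:rows, l_idx] = rgb[src, l_idx]
        return out
    return rgb
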
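"""Parametric tooth crowns and simulated evolution for testing.

The study's micro-CT scans are not available, so every pipeline stage
is exercised on generated inputs that reproduce their relevant
structure: a crown is a smooth height field over a superellipse domain
(controllable outline elongation and squareness) carrying 2-8
Gaussian cusp-like peaks of controllable position, height and width,
with the domain boundary at ``z = 0`` serving as the cervical outline.
Strain populations jitter cusp parameters, and trait matrices are
simulated under Brownian motion on a phylogeny.

Height-field crowns cannot express overhangs; multi-component section
geometry is covered separately by a constructed mushroom-profile
fixture in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import InputError
from .geometry import CervicalOutline
from .phylostats import as_tree, phylo_covariance

__all__ = [
    "ToothSpec",
    "make_tooth_mesh",
    "make_strain_sample",
    "simulate_bm_traits",
    "random_coalescent_tree",
]


@dataclass
class ToothSpec:
    """Parameters of one synthetic crown.

    ``outline`` gives superellipse semi-axes (a, b) and exponent; the
    crown surface is ``z = (1 - t^6) (base_height (1 - t^2) + bumps)``
    with ``t`` the normalized radial position, so the centre value is
    exactly ``base_height`` plus centred cusp heights and the boundary
    sits at ``z = 0``.
    """

    outline: tuple = (1.2, 0.8, 2.5)  # (a, b, exponent)
    cusps: list = field(
        default_factory=lambda: [
            (-0.55, 0.3, 0.9, 0.3),
            (0.0, 0.35, 1.0, 0.3),
            (0.55, 0.3, 0.9, 0.3),
            (-0.55, -0.3, 0.9, 0.3),
            (0.0, -0.35, 1.0, 0.3),
            (0.55, -0.3, 0.9, 0.3),
        ]
    )  # (x, y, height, width)
    base_height: float = 0.6
    mesh_resolution: int = 6000
    seed: int = 0

    def validate(self) -> None:
        a, b, n = self.outline
        if a <= 0 or b <= 0 or n <= 0:
            raise InputError("superellipse parameters must be positive")
        if not 0 < len(self.cusps) + 1:  # zero cusps allowed
            raise InputError("invalid cusp list")
        for x, y, h, w in self.cusps:
            if h <= 0 or w <= 0:
                raise InputError("cusp heights and widths must be positive")
            if (abs(x) / a) ** n + (abs(y) / b) ** n >= 1.0:
                raise InputError(f"cusp at ({x}, {y}) lies outside the outline")


def _superellipse_radius(phi: np.ndarray, a: float, b: float, n: float):
    return (np.abs(np.cos(phi) / a) ** n + np.abs(np.sin(phi) / b) ** n) ** (-1.0 / n)


def make_tooth_mesh(spec: ToothSpec):
    """Triangulate a crown height field.

    Returns ``(mesh, cervical_outline, buccal_anchor)``; the outline is
    the boundary ring (exactly ``z = 0``) and the anchor the boundary
    point in the +x direction.  Deterministic for a given spec.
    """
    spec.validate()
    a, b, n_exp = spec.outline

    n_seg = max(24, int(round(np.sqrt(spec.mesh_resolution))))
    n_ring = max(8, spec.mesh_resolution // (2 * n_seg))

    phi = 2.0 * np.pi * np.arange(n_seg) / n_seg
    rho = _superellipse_radius(phi, a, b, n_exp)

    verts = [np.array([0.0, 0.0, 0.0])]
    for m in range(1, n_ring + 1):
        t = m / n_ring
        x = t * rho * np.cos(phi)
        y = t * rho * np.sin(phi)
        verts.append(np.stack([x, y, np.zeros(n_seg)], axis=1))
    verts = np.vstack([verts[0][None, :], *verts[1:]])

    x, y = verts[:, 0], verts[:, 1]
    t = (np.abs(x / a) ** n_exp + np.abs(y / b) ** n_exp) ** (1.0 / n_exp)
    z = spec.base_height * (1.0 - t**2)
    for cx, cy, ch, cw in spec.cusps:
        z = z + ch * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * cw**2))
    z = z * (1.0 - np.minimum(t, 1.0) ** 6)
    verts[:, 2] = z

    faces = []
    ring0 = 1  # first ring start index
    for j in range(n_seg):  # centre fan
        faces.append([0, ring0 + j, ring0 + (j + 1) % n_seg])
    for m in range(n_ring - 1):
        s0 = 1 + m * n_seg
        s1 = 1 + (m + 1) * n_seg
        for j in range(n_seg):
            j1 = (j + 1) % n_seg
            faces.append([s0 + j, s1 + j, s1 + j1])
            faces.append([s0 + j, s1 + j1, s0 + j1])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    _ = mesh.vertex_normals

    boundary = verts[1 + (n_ring - 1) * n_seg :]
    outline = CervicalOutline(points=boundary.copy())
    anchor = boundary[0].copy()  # phi = 0: the +x boundary point
    return mesh, outline, anchor


def boundary_indices(spec: ToothSpec):
    """Vertex indices of the cervical boundary ring (for sidecar files)."""
    n_seg = max(24, int(round(np.sqrt(spec.mesh_resolution))))
    n_ring = max(8, spec.mesh_resolution // (2 * n_seg))
    start = 1 + (n_ring - 1) * n_seg
    return list(range(start, start + n_seg))


def make_strain_sample(spec: ToothSpec, n: int, noise: float, seed: int = 0):
    """Generate ``n`` within-strain variants of a crown spec.

    Cusp positions and heights are independently jittered with Gaussian
    noise of standard deviation ``noise`` (heights floored at 5% of the
    nominal value); widths are left fixed.  Deterministic per seed.
    """
    if n < 1:
        raise InputError("sample size must be >= 1")
    if noise < 0:
        raise InputError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cusps = []
        for cx, cy, ch, cw in spec.cusps:
            dx, dy, dh = rng.normal(0.0, noise, size=3)
            cusps.append((cx + dx, cy + dy, max(ch + dh, 0.05 * ch), cw))
        out.append(make_tooth_mesh(replace(spec, cusps=cusps, seed=spec.seed + i)))
    return out


def simulate_bm_traits(tree, p: int, rate: float = 1.0, seed: int = 0):
    """Tip trait matrix under Brownian motion with root state 0.

    Traits are independent with per-trait covariance ``rate * C`` where
    C is the shared-path-length matrix.  Returns ``(X, tip_labels)``.
    """
    if p < 1:
        raise InputError("p must be >= 1")
    if rate <= 0:
        raise InputError("rate must be positive")
    C, labels = phylo_covariance(tree)
    L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / len(C) * np.eye(len(C)))
    rng = np.random.default_rng(seed)
    X = np.sqrt(rate) * (L @ rng.standard_normal((len(C), p)))
    return X, labels


def random_coalescent_tree(n_tips: int, seed: int = 0, prefix: str = "t"):
    """Random ultrametric tree by sequential pairwise coalescence.

    A lightweight stand-in for the study's dated phylogeny: lineages
    merge in random pairs at exponentially distributed waiting times
    (rate = number of pairs).  Returns a dendropy Tree.
    """
    if n_tips < 2:
        raise InputError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    nodes = [f"{prefix}{i}" for i in range(n_tips)]
    heights = {nd: 0.0 for nd in nodes}
    newicks = {nd: nd for nd in nodes}
    time = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        time += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = f"{a}|{b}"
        newicks[parent] = (
            f"({newicks[a]}:{time - heights[a]:.10f},"
            f"{newicks[b]}:{time - heights[b]:.10f})"
        )
        heights[parent] = time
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [parent]
    return as_tree(newicks[nodes[0]] + ";")
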
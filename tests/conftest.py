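"""Shared fixtures: analytic meshes and small synthetic samples."""
import numpy as np
import pytest
import trimesh
from trimesh.intersections import slice_mesh_plane

from molarmap import CervicalOutline, orient_and_crop
from molarmap.synthetic import ToothSpec, make_strain_sample
from molarmap.workflows import specimen_to_mapset


def hemisphere_mesh(subdivisions=4, radius=1.0):
    """Open unit hemisphere (z >= 0) with its equator as free boundary."""
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return slice_mesh_plane(
        sphere, plane_normal=[0, 0, 1], plane_origin=[0, 0, -1e-9 * radius]
    )


def equator_outline(radius=1.0, n=64):
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return CervicalOutline(
        np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1)
    )


@pytest.fixture(scope="session")
def hemisphere_crown():
    """Oriented unit hemisphere (crown height 1, cut plane at z=0.2 of it)."""
    mesh = hemisphere_mesh()
    return orient_and_crop(mesh, equator_outline(), [1.5, 0.0, 0.0])


#: three well-separated cusp layouts (six, two and four cusps)
STRAIN_SPECS = {
    "six": ToothSpec(
        cusps=[(-0.55, 0.3, 0.9, 0.3), (0.0, 0.35, 1.0, 0.3), (0.55, 0.3, 0.9, 0.3),
               (-0.55, -0.3, 0.9, 0.3), (0.0, -0.35, 1.0, 0.3), (0.55, -0.3, 0.9, 0.3)],
        mesh_resolution=3000,
    ),
    "two": ToothSpec(
        cusps=[(-0.5, 0.0, 1.0, 0.35), (0.5, 0.0, 1.0, 0.35)], mesh_resolution=3000
    ),
    "four": ToothSpec(
        cusps=[(-0.5, 0.3, 0.8, 0.25), (0.5, 0.3, 0.8, 0.25),
               (-0.5, -0.3, 0.8, 0.25), (0.5, -0.3, 0.8, 0.25)],
        mesh_resolution=3000,
    ),
}


def strain_mapsets(n_per_strain=10, noise=0.02, grid=32):
    """Specimen MapSets for the three synthetic strains (seeded)."""
    mapsets = []
    for gi, (label, spec) in enumerate(STRAIN_SPECS.items()):
        sample = make_strain_sample(spec, n_per_strain, noise, seed=gi)
        for i, (mesh, outline, anchor) in enumerate(sample):
            mapsets.append(
                specimen_to_mapset(mesh, outline, anchor, grid, grid,
                                   specimen_id=f"{label}{i}", group=label)
            )
    return mapsets


@pytest.fixture(scope="session")
def three_strain_mapsets():
    return strain_mapsets()
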
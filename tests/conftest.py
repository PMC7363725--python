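"""Shared fixtures: small analytic phantoms and hand-built meshes."""

import numpy as np
import pytest

from oralsurf.meshing import TriangleMesh
from oralsurf.partition import Region
from oralsurf.phantom import Material, PhantomSpec, Sphere, generate_oral_phantom
from oralsurf.segmentation import BinaryMask


@pytest.fixture(scope="session")
def small_sphere_phantom():
    """Soft-tissue sphere, r = 5 mm at 0.3 mm spacing; fast but accurate."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        voxel_spacing_mm=(0.3, 0.3, 0.3),
        primitives=[
            Sphere(
                center=(7.0, 7.0, 7.0),
                radius=5.0,
                material=Material.SOFT_TISSUE,
                region=Region.MUCOSA,
            )
        ],
    )
    return generate_oral_phantom(spec, seed=0)


@pytest.fixture
def cube_mask_10mm():
    """Solid 10 mm cube at 1 mm spacing (analytic area 600 mm^2)."""
    data = np.zeros((14, 14, 14), dtype=bool)
    data[2:12, 2:12, 2:12] = True
    return BinaryMask(data, spacing_mm=(1.0, 1.0, 1.0))


CUBE_VERTICES = np.array(
    [
        [0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0],
        [0, 0, 10], [10, 0, 10], [10, 10, 10], [0, 10, 10],
    ],
    dtype=float,
)
# outward-oriented 12-triangle cube
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom (z=0)
        [4, 5, 6], [4, 6, 7],  # top (z=10)
        [0, 1, 5], [0, 5, 4],  # y=0
        [2, 3, 7], [2, 7, 6],  # y=10
        [1, 2, 6], [1, 6, 5],  # x=10
        [3, 0, 4], [3, 4, 7],  # x=0
    ],
    dtype=np.int64,
)


@pytest.fixture
def cube_mesh():
    """Explicit watertight 10 mm cube mesh, area exactly 600 mm^2."""
    return TriangleMesh(CUBE_VERTICES.copy(), CUBE_FACES.copy())


@pytest.fixture
def open_cube_mesh():
    """Cube mesh with its top face removed: one square boundary loop."""
    return TriangleMesh(CUBE_VERTICES.copy(), np.delete(CUBE_FACES, [2, 3], axis=0))
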
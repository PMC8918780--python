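import numpy as np
import pytest

from pancshell import PhantomSpec, VoxelGrid
from pancshell import phantom as ph
from pancshell._raster import paint_ball, paint_capsule

ANISO = (2.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Sparse phantom in a 120 µm box: fast, all channels, full truth."""
    spec = PhantomSpec(
        volume_shape=(60, 120, 120),
        spacing=ANISO,
        seed=2,
        epithelium=ph.EpitheliumParams(
            n_branches=2, branch_length=60, branch_radius=12, trunk_length=90, trunk_radius=16
        ),
        vessels=ph.VesselParams(n_tubes=2, radii=(3.0, 5.0), n_free_tubes=1, path_length=150),
        nuclei=ph.NucleiParams(
            counts={"epithelial": 80, "endothelial": 40, "mesenchymal": 60, "endocrine": 0},
            shell_weights={"mesenchymal": (0.68, 0.32, 0.0)},
        ),
    )
    volume, truth = ph.make_phantom(spec)
    return spec, volume, truth


def straight_tube_mask(radius, shape=(40, 60, 160), spacing=ANISO):
    """Tube along x at (z=40, y=30) µm, ends 10 µm from the volume borders."""
    mask = np.zeros(shape, dtype=bool)
    x1 = (shape[2] - 1) * spacing[2] - 10
    paint_capsule(mask, spacing, (10, 30, 40), (x1, 30, 40), radius)
    return VoxelGrid(mask, spacing)


def sphere_mask(radius, center, shape, spacing=ANISO):
    mask = np.zeros(shape, dtype=bool)
    paint_ball(mask, spacing, center, radius)
    return VoxelGrid(mask, spacing)
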
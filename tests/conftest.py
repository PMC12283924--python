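import numpy as np
import pytest

from softtet.material import Material
from softtet.tet_mesh import TetMesh, make_box_phantom

UNIT_TET_VERTS = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


@pytest.fixture
def unit_tet():
    """Single unit tetrahedron, density 6 so the tet mass is exactly 1 kg."""
    return TetMesh.from_arrays(UNIT_TET_VERTS, [[0, 1, 2, 3]], density=6.0)


@pytest.fixture
def small_box():
    """2x2x2-cell box phantom, 10 cm side, liver-like density."""
    return make_box_phantom(2, 2, 2, extent=(0.1, 0.1, 0.1), density=1000.0)


@pytest.fixture
def soft_material():
    """Softest SWE liver preset values."""
    return Material.from_young_poisson(2197.2, 0.4597, density=1000.0)


class ParticleSystem:
    """Minimal mesh stand-in for solver tests that need no tet topology."""

    def __init__(self, rest_positions, masses, pinned=()):
        self.rest_positions = np.asarray(rest_positions, float)
        masses = np.asarray(masses, float)
        self.vertex_mass = masses
        self.inv_mass = np.where(masses > 0, 1.0 / masses, 0.0)
        for i in pinned:
            self.inv_mass[i] = 0.0
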
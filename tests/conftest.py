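import numpy as np
import pytest
import trimesh

from capmorph.mesh_io import ColoredMesh, LandmarkSet
from capmorph.phantom import PhantomSpec, make_cap_scan, make_head
from capmorph.pose import ModuleGeometry

SPHERE_R = 100.0


@pytest.fixture(scope="session")
def sphere_mesh():
    """Analytic sphere phantom, radius 100 mm."""
    ico = trimesh.creation.icosphere(subdivisions=4, radius=SPHERE_R)
    return ColoredMesh(
        ico.vertices, ico.faces, np.full((len(ico.vertices), 3), 0.5)
    )


@pytest.fixture(scope="session")
def sphere_landmarks():
    return LandmarkSet(
        nasion=[0.0, SPHERE_R, 0.0],
        inion=[0.0, -SPHERE_R, 0.0],
        left_preauricular=[-SPHERE_R, 0.0, 0.0],
        right_preauricular=[SPHERE_R, 0.0, 0.0],
    )


@pytest.fixture(scope="session")
def geometry():
    return ModuleGeometry()


@pytest.fixture(scope="session")
def default_truth():
    """Default phantom head, seed 1 (scan built lazily by default_scan)."""
    return make_head(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def default_scan(default_truth, geometry):
    return make_cap_scan(default_truth, default_truth.spec, geometry)


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free default phantom (seed 1)."""
    return make_head(PhantomSpec(seed=1, noise_sigma=0.0))


@pytest.fixture(scope="session")
def clean_scan(clean_truth, geometry):
    return make_cap_scan(clean_truth, clean_truth.spec, geometry)
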
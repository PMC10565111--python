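import numpy as np
import pytest
import trimesh

from lanternjump import mesh_mechanics as mm


@pytest.fixture(scope="session")
def default_geometry():
    return mm.PostureGeometry()


@pytest.fixture(scope="session")
def posture_meshes(default_geometry):
    return {label: mm.build_nymph_mesh(default_geometry, label)
            for label in ("legs_tucked", "legs_extended")}


@pytest.fixture(scope="session")
def posture_props(posture_meshes):
    return {label: mm.compute_rigid_body_properties(mesh, 28.4)
            for label, mesh in posture_meshes.items()}


@pytest.fixture(scope="session")
def cube_mesh():
    return trimesh.creation.box(extents=[10.0, 10.0, 10.0])


@pytest.fixture(scope="session")
def icosphere_mesh():
    return trimesh.creation.icosphere(subdivisions=3, radius=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
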